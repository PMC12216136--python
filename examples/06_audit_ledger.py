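"""Tamper-evident audit ledger over analysis artifacts.

Appends payload digests to a hash-chained ledger, verifies it, then
simulates a retroactive edit and shows it being detected.
"""

from swarmdx import Ledger, append_record, verify_chain

ledger = Ledger()
for payload in (b"cohort.csv digest payload", b"selected-features payload", b"report payload"):
    block = append_record(ledger, payload)
    print(f"block {block.index}: payload {block.payload_digest[:12]}... "
          f"chain {block.block_hash[:12]}...")

ok, bad = verify_chain(ledger)
print(f"chain valid: {ok}")

ledger.blocks[1].payload_digest = "0" * 64  # retroactive edit
ok, bad = verify_chain(ledger)
print(f"after tampering with block 1 -> valid: {ok}, first bad index: {bad}")
# Any single-bit change to any stored field breaks the recomputed hashes, so
# post-hoc edits to committed artifacts are always detectable.
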