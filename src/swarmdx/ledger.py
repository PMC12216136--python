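"""Minimal hash-chained, tamper-evident record store.

A single-writer audit ledger: each block commits to the SHA-256 digest of its
payload and to the previous block's hash, so any retroactive edit anywhere in
the chain is detectable.  Only digests are stored — raw patient data stays in
its external file — which keeps the ledger small and free of sensitive
content by construction.  There is no networking, consensus or signature
scheme; this is an append-only integrity log, not a distributed blockchain.

Serialization is canonical length-prefixed field concatenation (8-byte
big-endian length + UTF-8 bytes per field), giving bit-exact hashes across
platforms.  The on-disk format is JSON lines, one block per line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone

__all__ = ["Block", "Ledger", "GENESIS_PREV", "append_record", "verify_chain"]

GENESIS_PREV = "0" * 64


def _canonical(fields: list[str]) -> bytes:
    out = b""
    for f in fields:
        raw = f.encode("utf-8")
        out += len(raw).to_bytes(8, "big") + raw
    return out


def _block_hash(index: int, timestamp: str, payload_digest: str, prev_hash: str) -> str:
    return hashlib.sha256(
        _canonical([str(index), timestamp, payload_digest, prev_hash])
    ).hexdigest()


@dataclass
class Block:
    index: int
    timestamp: str
    payload_digest: str
    prev_hash: str
    block_hash: str

    def recomputed_hash(self) -> str:
        return _block_hash(self.index, self.timestamp, self.payload_digest, self.prev_hash)


class TamperError(RuntimeError):
    """Refused operation on a ledger that fails verification."""


@dataclass
class Ledger:
    blocks: list = None

    def __post_init__(self) -> None:
        if self.blocks is None:
            self.blocks = []

    def __len__(self) -> int:
        return len(self.blocks)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for b in self.blocks:
                fh.write(json.dumps(asdict(b), sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "Ledger":
        blocks = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    blocks.append(Block(**json.loads(line)))
        return cls(blocks)


def append_record(ledger: Ledger, payload: bytes, timestamp: str | None = None) -> Block:
    """Append a block committing to ``payload``'s SHA-256 digest.

    The ledger must verify before the append is accepted; an inconsistent
    chain refuses further writes.
    """
    ok, bad = verify_chain(ledger)
    if not ok:
        raise TamperError(f"ledger fails verification at block {bad}; append refused")
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat()
    index = len(ledger.blocks)
    prev = ledger.blocks[-1].block_hash if ledger.blocks else GENESIS_PREV
    digest = hashlib.sha256(payload).hexdigest()
    block = Block(index, timestamp, digest, prev, _block_hash(index, timestamp, digest, prev))
    ledger.blocks.append(block)
    return block


def verify_chain(ledger: Ledger) -> tuple[bool, int | None]:
    """Recompute every hash and link; return (valid, first_bad_index)."""
    prev = GENESIS_PREV
    for i, b in enumerate(ledger.blocks):
        if b.index != i or b.prev_hash != prev or b.recomputed_hash() != b.block_hash:
            return False, i
        prev = b.block_hash
    return True, None
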