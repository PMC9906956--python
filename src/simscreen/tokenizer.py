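"""SMILES tokenization and integer encoding.

Atom-level regex tokenization: bracket expressions, two-letter halogens and
`%dd` ring closures are single tokens; everything else is one character.
Concatenating the tokens always reproduces the input string, so
encode/decode round-trips are lossless.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIAL_TOKENS = (PAD, BOS, EOS, UNK)
PAD_ID, BOS_ID, EOS_ID, UNK_ID = 0, 1, 2, 3

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Cl|Br|%\d{2}|[BCNOPSFIbcnops]|[0-9]|[=#\-+\\/()@.~$:*])"
)


class TokenizationError(ValueError):
    pass


class SequenceLengthError(ValueError):
    pass


def tokenize(smiles: str) -> list:
    """Split a SMILES string into tokens; lossless by construction."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens, pos = [], 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"cannot tokenize {smiles!r} at position {pos} ({smiles[pos]!r})")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass
class Vocabulary:
    """Token <-> id map with PAD/BOS/EOS/UNK pinned at ids 0-3."""

    token_to_id: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.token_to_id:
            self.token_to_id = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
        for i, t in enumerate(SPECIAL_TOKENS):
            if self.token_to_id.get(t) != i:
                raise ValueError(f"special token {t!r} must have id {i}")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        if len(self.id_to_token) != len(self.token_to_id):
            raise ValueError("token_to_id is not bijective")

    def __len__(self):
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def token(self, idx: int) -> str:
        if idx not in self.id_to_token:
            raise ValueError(f"id {idx} outside vocabulary (size {len(self)})")
        return self.id_to_token[idx]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.token_to_id, indent=0, sort_keys=True))

    @classmethod
    def load(cls, path) -> "Vocabulary":
        return cls(token_to_id=json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        import hashlib
        return hashlib.sha256(
            json.dumps(self.token_to_id, sort_keys=True).encode()).hexdigest()[:16]


def build_vocabulary(dataset) -> Vocabulary:
    """Vocabulary over all tokens in the dataset, sorted for determinism."""
    if not dataset:
        raise ValueError("dataset is empty")
    seen = set()
    for rec in dataset:
        smiles = rec.smiles if hasattr(rec, "smiles") else rec
        seen.update(tokenize(smiles))
    mapping = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
    for tok in sorted(seen):
        mapping[tok] = len(mapping)
    return Vocabulary(token_to_id=mapping)


@dataclass
class TokenSequence:
    """BOS + token ids + EOS, PAD-padded to a fixed max_len."""

    ids: list
    length: int  # BOS..EOS inclusive, excluding padding

    def __post_init__(self):
        if self.ids[0] != BOS_ID:
            raise ValueError("sequence must begin with BOS")
        if EOS_ID in self.ids:
            eos_at = self.ids.index(EOS_ID)
            if eos_at != self.length - 1:
                raise ValueError("EOS must terminate the unpadded span")
            if any(i != PAD_ID for i in self.ids[eos_at + 1:]):
                raise ValueError("only PAD allowed after EOS")


def encode(smiles: str, vocab: Vocabulary, max_len: int,
           mol_id: str | None = None) -> TokenSequence:
    tokens = tokenize(smiles)
    if len(tokens) + 2 > max_len:
        who = f" ({mol_id})" if mol_id else ""
        raise SequenceLengthError(
            f"SMILES{who} needs {len(tokens) + 2} positions > max_len {max_len}")
    ids = [BOS_ID]
    for tok in tokens:
        if tok not in vocab:
            logger.warning("unknown token %r in %r -> UNK", tok, smiles)
        ids.append(vocab.id(tok))
    ids.append(EOS_ID)
    length = len(ids)
    ids.extend([PAD_ID] * (max_len - length))
    return TokenSequence(ids=ids, length=length)


def decode(seq: TokenSequence | Sequence[int], vocab: Vocabulary) -> str:
    """Token texts between BOS and the first EOS; specials omitted."""
    ids = seq.ids if isinstance(seq, TokenSequence) else list(seq)
    out = []
    started = False
    for idx in ids:
        idx = int(idx)
        if idx == BOS_ID and not started:
            started = True
            continue
        if idx == EOS_ID:
            return "".join(out)
        if idx == PAD_ID:
            continue
        out.append(vocab.token(idx))
    logger.warning("sequence without EOS; decoded to end")
    return "".join(out)


def shifted_pair(seq: TokenSequence) -> tuple:
    """(decoder input without EOS, decoder target without BOS), right-shifted."""
    ids = list(seq.ids)
    eos_at = seq.length - 1
    dec_in = ids[:eos_at] + [PAD_ID] * (len(ids) - 1 - eos_at)
    target = ids[1:]
    return dec_in, target


def encode_batch(smiles_list: Iterable[str], vocab: Vocabulary,
                 max_len: int) -> "np.ndarray":
    import numpy as np
    return np.array([encode(s, vocab, max_len).ids for s in smiles_list],
                    dtype=np.int64)
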