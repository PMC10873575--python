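"""5-mer tokenization of 13-base motifs.

A nanopore reads roughly five bases at a time, so the sequence branch of the
model consumes overlapping 5-mers: a 13-base motif becomes 9 tokens (windows
[0..4] through [8..12], stride 1).  The vocabulary is the 4^5 = 1024 ACGT
5-mers in lexicographic order, followed by an UNK id for any window
containing an ambiguous base (N) and a PAD id reserved for future use.  Ids
are a pure function of the k-mer string, identical across processes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

__all__ = ["K", "N_TOKENS", "TokenizedMotif", "build_vocab", "tokenize",
           "save_vocab", "load_vocab", "vocab_hash"]

K = 5
N_TOKENS = 13 - K + 1  # 9 overlapping windows per motif
_BASES = "ACGT"


@dataclass(frozen=True)
class TokenizedMotif:
    """The 9 token ids of one motif, plus the vocabulary size used."""

    token_ids: tuple[int, ...]
    vocab_size: int

    def __post_init__(self) -> None:
        if len(self.token_ids) != N_TOKENS:
            raise ValueError(f"expected {N_TOKENS} tokens")
        if not all(0 <= t < self.vocab_size for t in self.token_ids):
            raise ValueError("token id out of range")


def build_vocab() -> dict[str, int]:
    """Map each ACGT 5-mer to a stable id (lexicographic), plus UNK and PAD."""
    vocab = {"".join(kmer): i
             for i, kmer in enumerate(product(_BASES, repeat=K))}
    vocab["<UNK>"] = len(vocab)   # any 5-mer containing N
    vocab["<PAD>"] = len(vocab)
    return vocab


_VOCAB = build_vocab()
UNK_ID = _VOCAB["<UNK>"]
PAD_ID = _VOCAB["<PAD>"]
VOCAB_SIZE = len(_VOCAB)


def tokenize(motif: str, vocab: dict[str, int] | None = None) -> TokenizedMotif:
    """Tokenize a 13-base motif into its 9 overlapping 5-mer ids."""
    if vocab is None:
        vocab = _VOCAB
    if len(motif) != 13:
        raise ValueError(f"motif must have length 13, got {len(motif)}")
    unk = vocab["<UNK>"]
    ids = tuple(vocab.get(motif[i:i + K], unk) for i in range(N_TOKENS))
    return TokenizedMotif(token_ids=ids, vocab_size=len(vocab))


def save_vocab(vocab: dict[str, int], path: str | Path) -> None:
    """Dump the vocabulary as a two-column (kmer, id) text file."""
    with open(path, "w") as fh:
        for kmer, idx in sorted(vocab.items(), key=lambda kv: kv[1]):
            fh.write(f"{kmer}\t{idx}\n")


def load_vocab(path: str | Path) -> dict[str, int]:
    vocab: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            kmer, idx = line.split("\t")
            vocab[kmer] = int(idx)
    return vocab


def vocab_hash(vocab: dict[str, int] | None = None) -> str:
    """Order-insensitive fingerprint used to tie checkpoints to a vocabulary."""
    import hashlib

    if vocab is None:
        vocab = _VOCAB
    digest = hashlib.sha256()
    for kmer, idx in sorted(vocab.items()):
        digest.update(f"{kmer}:{idx};".encode())
    return digest.hexdigest()[:16]
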