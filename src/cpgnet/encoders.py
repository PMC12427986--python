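"""One-hot sequence encodings: monomer (L x 4), dimer ((L-1) x 8), dimer16.

Monomer encoding maps each base to a length-4 indicator in the fixed order
(A, C, G, T).  Dimer encoding represents each overlapping dinucleotide as
the concatenation of the two constituent monomer vectors, giving 8 channels
and L-1 rows for an L-base window; this is the canonical scheme here.  A
16-channel variant (one indicator per dinucleotide) is available as
``dimer16``.  Ambiguous bases (N) yield all-zero rows so tensor shapes stay
determined by the window width alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .seqdata import CLASS_ORDER, SequenceWindow

BASE_ORDER = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class EncodingScheme:
    name: str
    channels: int
    row_count: Callable[[int], int]

    def encode(self, seq: str) -> np.ndarray:
        return _ENCODE_FN[self.name](seq)


def encode_monomer(seq: str) -> np.ndarray:
    """Encode a sequence as an L x 4 one-hot matrix (A, C, G, T order)."""
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq):
        if ch == "N":
            continue
        j = _BASE_INDEX.get(ch)
        if j is None:
            raise ValueError(f"invalid base {ch!r} at position {i}")
        out[i, j] = 1.0
    return out


def encode_dimer(seq: str) -> np.ndarray:
    """Encode overlapping dinucleotides as an (L-1) x 8 matrix.

    Row i is the monomer one-hot of seq[i] followed by that of seq[i+1];
    a dimer containing N is an all-zero row.
    """
    if len(seq) < 2:
        raise ValueError("dimer encoding needs a sequence of length >= 2")
    mono = encode_monomer(seq)
    out = np.concatenate([mono[:-1], mono[1:]], axis=1)
    # zero the whole row when either base is ambiguous
    valid = (mono[:-1].sum(axis=1) > 0) & (mono[1:].sum(axis=1) > 0)
    out[~valid] = 0.0
    return out


def encode_dimer16(seq: str) -> np.ndarray:
    """Encode overlapping dinucleotides as an (L-1) x 16 indicator matrix."""
    if len(seq) < 2:
        raise ValueError("dimer encoding needs a sequence of length >= 2")
    out = np.zeros((len(seq) - 1, 16), dtype=np.float32)
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        if a == "N" or b == "N":
            continue
        try:
            out[i, 4 * _BASE_INDEX[a] + _BASE_INDEX[b]] = 1.0
        except KeyError as exc:
            raise ValueError(f"invalid base near position {i}") from exc
    return out


def decode_monomer(matrix: np.ndarray) -> str:
    """Invert monomer encoding (argmax per row; zero rows decode to N)."""
    out = []
    for row in matrix:
        out.append("N" if row.sum() == 0 else BASE_ORDER[int(np.argmax(row))])
    return "".join(out)


MONOMER = EncodingScheme("monomer", 4, lambda L: L)
DIMER = EncodingScheme("dimer", 8, lambda L: L - 1)
DIMER16 = EncodingScheme("dimer16", 16, lambda L: L - 1)

SCHEMES = {s.name: s for s in (MONOMER, DIMER, DIMER16)}
_ENCODE_FN = {
    "monomer": encode_monomer,
    "dimer": encode_dimer,
    "dimer16": encode_dimer16,
}


def get_scheme(name: str) -> EncodingScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown encoding scheme {name!r}; choose from {sorted(SCHEMES)}"
        ) from None


@dataclass
class EncodedDataset:
    """A stacked n x L' x C feature tensor with aligned labels and site ids.

    ``labels`` are integer class indices following CLASS_ORDER
    (0 = unmethylated, 1 = methylated).
    """

    features: np.ndarray
    labels: np.ndarray
    scheme: EncodingScheme
    site_ids: list[str]
    width: int

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (n == len(self.labels) == len(self.site_ids)):
            raise ValueError("features, labels and site_ids disagree on n")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def label_names(self) -> list[str]:
        return [CLASS_ORDER[i] for i in self.labels]

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            scheme=self.scheme,
            site_ids=[self.site_ids[int(i)] for i in idx],
            width=self.width,
        )


def encode_batch(
    windows: Sequence[SequenceWindow], scheme: EncodingScheme | str
) -> EncodedDataset:
    """Encode windows (all of one width) into an n x row_count(W) x C tensor."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if len(windows) == 0:
        raise ValueError("cannot encode an empty batch")
    widths = {w.width for w in windows}
    if len(widths) != 1:
        raise ValueError(f"mixed window widths {sorted(widths)}")
    width = widths.pop()
    feats = np.stack([scheme.encode(w.seq) for w in windows])
    labels = np.array(
        [CLASS_ORDER.index(w.site.label) for w in windows], dtype=np.int64
    )
    ids = [f"{w.site.chrom}:{w.site.pos}" for w in windows]
    return EncodedDataset(feats, labels, scheme, ids, width)


def save_dataset(ds: EncodedDataset, path: str | Path) -> None:
    """Write the tensor (.npz) plus a sidecar JSON manifest."""
    path = Path(path)
    np.savez_compressed(path, features=ds.features, labels=ds.labels)
    manifest = {
        "scheme": ds.scheme.name,
        "width": ds.width,
        "n": len(ds),
        "shape": list(ds.features.shape),
        "site_ids": ds.site_ids,
        "class_order": list(CLASS_ORDER),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(path: str | Path) -> EncodedDataset:
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    arrays = np.load(npz)
    with open(npz.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    return EncodedDataset(
        features=arrays["features"],
        labels=arrays["labels"],
        scheme=get_scheme(manifest["scheme"]),
        site_ids=list(manifest["site_ids"]),
        width=int(manifest["width"]),
    )
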