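"""Genome and methylation-table ingestion, labeling, windowing and splitting.

The pipeline starts from a reference sequence (FASTA) and a site-level CpG
methylation table (TSV with per-site methylation percentages, the output of
bisulfite/RRBS processing).  Sites are binarized at the 50% beta threshold,
fixed-width sequence windows are cut around each CpG, and the dataset is
partitioned 70:20:10 into train/test/validation.

Coordinate conventions
----------------------
Internally all positions are 0-based indices of the C of a CG dinucleotide.
Input tables may be 0-based (``bed0``, the ENCODE RRBS convention) or
1-based (``tsv1``); the reader normalizes.  A window of even width ``W`` is
the half-open interval ``[pos - W/2, pos + W/2)`` so the C sits at offset
``W/2`` and the full CG is always inside the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
SUPPORTED_WIDTHS = (100, 200, 300)
METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
#: class order used throughout: index 0 = unmethylated, 1 = methylated
CLASS_ORDER = (UNMETHYLATED, METHYLATED)
BETA_THRESHOLD = 50.0

TABLE_COLUMNS = ("chrom", "pos", "beta_percent")


class FastaFormatError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


@dataclass
class GenomeSequence:
    """One chromosome/contig: an uppercase string over {A,C,G,T,N}."""

    name: str
    residues: str
    n_ambiguous_normalized: int = 0

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in {self.name!r}")


@dataclass
class CpGSite:
    """A CG locus: 0-based position of the C, beta in percent, optional label."""

    chrom: str
    pos: int
    beta: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 100.0:
            raise ValueError(f"beta {self.beta} outside [0, 100]")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.label is None:
            self.label = label_site(self.beta)
        elif self.label != label_site(self.beta):
            raise ValueError(
                f"label {self.label!r} inconsistent with beta {self.beta}"
            )


@dataclass
class SequenceWindow:
    """Fixed-width sequence context centered on the C of a CpG site."""

    site: CpGSite
    width: int
    seq: str
    center_offset: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.center_offset < 0:
            self.center_offset = self.width // 2
        if len(self.seq) != self.width:
            raise ValueError(
                f"window length {len(self.seq)} != width {self.width}"
            )
        if self.seq[self.center_offset : self.center_offset + 2] != "CG":
            raise ValueError("window center is not a CG dinucleotide")


@dataclass
class SplitSpec:
    """70:20:10 train/test/validation fractions plus a shuffle seed."""

    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be nonnegative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions {self.fractions} do not sum to 1")


def label_site(beta: float) -> str:
    """Binarize a methylation percentage at the 50% threshold (inclusive)."""
    if not 0.0 <= beta <= 100.0:
        raise ValueError(f"beta {beta} outside [0, 100]")
    return METHYLATED if beta >= BETA_THRESHOLD else UNMETHYLATED


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into :class:`GenomeSequence` records.

    Residues are uppercased; characters outside {A,C,G,T,N} are mapped to N
    and counted per record (a warning is logged with the total).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_preamble(path)
    records = []
    total_normalized = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        n_bad = sum(1 for ch in raw if ch not in VALID_BASES)
        if n_bad:
            raw = "".join(ch if ch in VALID_BASES else "N" for ch in raw)
            total_normalized += n_bad
        records.append(
            GenomeSequence(name=rec.id, residues=raw, n_ambiguous_normalized=n_bad)
        )
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    if total_normalized:
        logger.warning(
            "%s: %d non-ACGTN characters normalized to N", path, total_normalized
        )
    return records


def _check_fasta_preamble(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:30]!r}"
                )
            return
    raise FastaFormatError(f"{path}: empty file")


def read_methylation_table(
    path: str | Path, dialect: str = "bed0"
) -> list[CpGSite]:
    """Read a ``chrom pos beta_percent`` TSV into :class:`CpGSite` records.

    ``dialect='bed0'`` positions are 0-based (ENCODE RRBS convention);
    ``dialect='tsv1'`` positions are 1-based and get shifted.  Rows whose
    beta falls outside [0, 100] are rejected with a logged reason.
    """
    import pandas as pd

    if dialect not in ("bed0", "tsv1"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first.split("\t")[0].strip().lower() in ("chrom", "chr", "#chrom")
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=None if has_header else list(TABLE_COLUMNS),
        float_precision="round_trip",
    )
    if has_header:
        df.columns = [c.lstrip("#").strip().lower() for c in df.columns]
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    pos = pd.to_numeric(df["pos"], errors="raise").astype(int)
    beta = pd.to_numeric(df["beta_percent"], errors="raise").astype(float)
    if dialect == "tsv1":
        pos = pos - 1
    if (pos < 0).any():
        bad = int((pos < 0).sum())
        raise ValueError(f"{path}: {bad} negative positions after normalization")
    sites: list[CpGSite] = []
    n_rejected = 0
    for chrom, p, b in zip(df["chrom"], pos, beta):
        if not 0.0 <= b <= 100.0:
            n_rejected += 1
            logger.warning("%s:%d rejected: beta %.4g outside [0, 100]", chrom, p, b)
            continue
        sites.append(CpGSite(chrom=str(chrom), pos=int(p), beta=float(b)))
    if n_rejected:
        logger.warning("%s: rejected %d rows with out-of-range beta", path, n_rejected)
    return sites


def write_methylation_table(
    sites: Iterable[CpGSite], path: str | Path, dialect: str = "bed0"
) -> None:
    """Write sites back out in the TSV dialect accepted by the reader."""
    if dialect not in ("bed0", "tsv1"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    shift = 1 if dialect == "tsv1" else 0
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos + shift}\t{s.beta!r}\n")


def validate_site(genome: GenomeSequence, site: CpGSite) -> bool:
    """True iff the site indexes a CG dinucleotide in the genome."""
    return genome.residues[site.pos : site.pos + 2] == "CG"


def extract_window(
    genome: GenomeSequence,
    site: CpGSite,
    width: int,
    validate: bool = True,
) -> SequenceWindow | None:
    """Cut the ``[pos - W/2, pos + W/2)`` window around a site.

    Returns None (with a logged reason) when the window overruns a
    chromosome end or, with ``validate``, when the site is not a CG.
    """
    if width % 2 != 0 or width <= 0:
        raise ValueError(f"window width must be even and positive, got {width}")
    if site.chrom != genome.name:
        raise ValueError(f"site chrom {site.chrom!r} != genome {genome.name!r}")
    half = width // 2
    start, stop = site.pos - half, site.pos + half
    if start < 0 or stop > genome.length:
        logger.info("site %s:%d skipped: window overruns chromosome", site.chrom, site.pos)
        return None
    if validate and not validate_site(genome, site):
        logger.info("site %s:%d skipped: not a CG dinucleotide", site.chrom, site.pos)
        return None
    return SequenceWindow(site=site, width=width, seq=genome.residues[start:stop])


def extract_windows(
    genomes: Sequence[GenomeSequence] | GenomeSequence,
    sites: Iterable[CpGSite],
    width: int,
    validate: bool = True,
    max_n_fraction: float = 0.10,
) -> tuple[list[SequenceWindow], int]:
    """Batch window extraction; returns (windows, number of skipped sites).

    Sites whose window contains more than ``max_n_fraction`` ambiguous (N)
    bases are skipped, since their encodings would be mostly zero rows.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    by_name = {g.name: g for g in genomes}
    windows: list[SequenceWindow] = []
    skipped = 0
    for site in sites:
        genome = by_name.get(site.chrom)
        if genome is None:
            logger.info("site %s:%d skipped: unknown chromosome", site.chrom, site.pos)
            skipped += 1
            continue
        w = extract_window(genome, site, width, validate=validate)
        if w is None or w.seq.count("N") > max_n_fraction * width:
            skipped += 1
            continue
        windows.append(w)
    return windows, skipped


def subsample_sites(
    sites: Sequence[CpGSite], n: int, seed: int
) -> list[CpGSite]:
    """Stratified random subsample preserving the class ratio within ±1 site."""
    if n > len(sites):
        raise ValueError(f"requested {n} sites but only {len(sites)} available")
    rng = np.random.default_rng(seed)
    meth_idx = [i for i, s in enumerate(sites) if s.label == METHYLATED]
    unmeth_idx = [i for i, s in enumerate(sites) if s.label == UNMETHYLATED]
    n_meth = int(round(n * len(meth_idx) / len(sites)))
    n_meth = min(max(n_meth, n - len(unmeth_idx)), len(meth_idx), n)
    chosen = list(rng.choice(meth_idx, size=n_meth, replace=False)) + list(
        rng.choice(unmeth_idx, size=n - n_meth, replace=False)
    )
    chosen.sort()
    return [sites[i] for i in chosen]


def split_dataset(
    n_items: int, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-deterministic 70:20:10 partition into train/test/validation indices.

    Sizes are floor(f0*n) and floor(f1*n) with the remainder going to
    validation, which gives exactly 3500/1000/500 at n = 5000.
    """
    if n_items < 3 and all(f > 0 for f in spec.fractions):
        raise ValueError(f"need at least 3 items to split, got {n_items}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_items)
    n_train = int(np.floor(spec.fractions[0] * n_items))
    n_test = int(np.floor(spec.fractions[1] * n_items))
    return (
        order[:n_train],
        order[n_train : n_train + n_test],
        order[n_train + n_test :],
    )


def write_split_manifest(
    site_ids: Sequence[str],
    splits: tuple[np.ndarray, np.ndarray, np.ndarray],
    path: str | Path,
) -> None:
    """Write a ``site_id  split`` TSV recording the partition."""
    names = ("train", "test", "validation")
    assignment: dict[int, str] = {}
    for name, idx in zip(names, splits):
        for i in idx:
            assignment[int(i)] = name
    with open(path, "w") as fh:
        fh.write("site_id\tsplit\n")
        for i, sid in enumerate(site_ids):
            fh.write(f"{sid}\t{assignment[i]}\n")
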