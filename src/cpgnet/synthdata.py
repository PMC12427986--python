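"""Synthetic methylome generation with a planted, learnable sequence rule.

The generator emulates the two real inputs of the pipeline — a reference
sequence (FASTA) and a site-level CpG methylation table — so every later
stage can be exercised without downloads.  Methylation is driven by a
planted motif: CpG sites with the motif nearby draw their beta value from
a high-mean noise distribution, sites without it from a low-mean one.
Because the motif is a local sequence feature inside the extraction
window, a sequence-based classifier can in principle recover the labels,
and the achievable ceiling (Bayes accuracy) follows in closed form from
the two beta distributions and the 50% labeling threshold.

Beta noise is a scaled Beta distribution on [0, 100] parameterized by its
mean and a concentration (larger = tighter); ``beta_spread = inf`` is the
noiseless limit where every beta equals its mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .seqdata import (
    BETA_THRESHOLD,
    CpGSite,
    GenomeSequence,
    METHYLATED,
    write_methylation_table,
)

DEFAULT_MOTIF = "TATAAT"


@dataclass
class SyntheticRule:
    """The planted sequence→methylation rule.

    ``motif_window`` is the radius around the CpG (in bp) within which a
    motif occurrence counts; keep it at or below half the extraction
    window width so the feature is visible to the classifier.
    """

    motif: str = DEFAULT_MOTIF
    beta_high_mean: float = 80.0
    beta_low_mean: float = 20.0
    beta_spread: float = 6.0
    motif_window: int = 50

    def __post_init__(self) -> None:
        if not self.beta_high_mean > BETA_THRESHOLD > self.beta_low_mean:
            raise ValueError(
                "beta_high_mean must exceed 50 and beta_low_mean fall below it"
            )
        if len(self.motif) >= self.motif_window:
            raise ValueError("motif must be shorter than motif_window")
        if self.beta_spread <= 0:
            raise ValueError("beta_spread must be positive")

    def prob_methylated(self, high: bool) -> float:
        """P(beta >= 50) under the high- or low-mean noise distribution."""
        mean = self.beta_high_mean if high else self.beta_low_mean
        if math.isinf(self.beta_spread):
            return 1.0 if mean >= BETA_THRESHOLD else 0.0
        mu = mean / 100.0
        return float(stats.beta.sf(0.5, mu * self.beta_spread,
                                   (1 - mu) * self.beta_spread))

    def draw_beta(self, high: bool, rng: np.random.Generator) -> float:
        mean = self.beta_high_mean if high else self.beta_low_mean
        if math.isinf(self.beta_spread):
            return mean
        mu = mean / 100.0
        return 100.0 * float(
            rng.beta(mu * self.beta_spread, (1 - mu) * self.beta_spread)
        )


@dataclass
class SyntheticMethylome:
    genome: GenomeSequence
    sites: list[CpGSite]
    rule: SyntheticRule
    seed: int
    bayes_accuracy: float = field(default=0.0)


def generate_genome(
    length: int, gc_content: float = 0.5, seed: int = 0, name: str = "chrSim"
) -> GenomeSequence:
    """I.i.d. random sequence with the requested GC fraction (split evenly)."""
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content {gc_content} outside (0, 1)")
    if length < 1000:
        raise ValueError("genome length must be at least 1000 bp")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return GenomeSequence(name=name, residues="".join(bases))


def _motif_near(seq: np.ndarray, motif: str, pos: int, radius: int) -> bool:
    """True iff the motif starts within [pos - radius, pos + radius - len]."""
    m = np.frombuffer(motif.encode(), dtype="S1")
    lo = max(pos - radius, 0)
    hi = min(pos + radius - len(motif), len(seq) - len(motif))
    for start in range(lo, hi + 1):
        if (seq[start : start + len(motif)] == m).all():
            return True
    return False


def plant_methylome(
    genome: GenomeSequence,
    n_sites: int,
    rule: SyntheticRule | None = None,
    seed: int = 0,
    inject_fraction: float = 0.5,
    n_motif_copies: int = 3,
    min_separation: int | None = None,
) -> SyntheticMethylome:
    """Select CpG sites and plant the motif rule.

    The motif is injected into the genome near ``inject_fraction`` of the
    selected sites so the two classes stay balanced; after injection each
    site's motif status is re-read from the final sequence, so the planted
    rule is exactly consistent with the emitted genome.  Injection places a
    small cluster of ``n_motif_copies`` occurrences, mirroring how
    methylation-associated sequence elements (CpG density, binding-site
    clusters) occur as local enrichments rather than single faint hits;
    the labeling rule itself only asks whether the motif occurs at all.
    Sites keep a minimum separation (default: 2x the motif window) so the
    cluster of one site cannot leak into another's neighborhood.
    """
    rule = rule or SyntheticRule()
    if min_separation is None:
        min_separation = 2 * rule.motif_window
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(genome.residues.encode(), dtype="S1").copy()
    margin = rule.motif_window + len(rule.motif) + 2

    cg = np.nonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))[0]
    cg = cg[(cg >= margin) & (cg < len(seq) - margin)]
    # greedy spacing filter over a shuffled candidate order
    candidates = rng.permutation(cg)
    chosen: list[int] = []
    occupied = np.zeros(len(seq), dtype=bool)
    for p in candidates:
        if not occupied[max(p - min_separation, 0) : p + min_separation].any():
            chosen.append(int(p))
            occupied[p] = True
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:
        raise ValueError(
            f"genome supports only {len(chosen)} well-separated CpG sites, "
            f"{n_sites} requested"
        )
    chosen.sort()

    inject = rng.random(n_sites) < inject_fraction
    motif = np.frombuffer(rule.motif.encode(), dtype="S1")
    for p, do_inject in zip(chosen, inject):
        if not do_inject:
            continue
        # place the motif inside the radius but never across the CG itself
        starts = [
            s
            for s in range(p - rule.motif_window, p + rule.motif_window - len(motif) + 1)
            if s + len(motif) <= p or s >= p + 2
        ]
        k = min(n_motif_copies, len(starts))
        for start in rng.choice(starts, size=k, replace=False):
            seq[int(start) : int(start) + len(motif)] = motif

    final = GenomeSequence(name=genome.name, residues=seq.tobytes().decode())
    sites = []
    n_with_motif = 0
    for p in chosen:
        has_motif = _motif_near(seq, rule.motif, p, rule.motif_window)
        n_with_motif += has_motif
        beta = min(max(rule.draw_beta(has_motif, rng), 0.0), 100.0)
        sites.append(CpGSite(chrom=final.name, pos=p, beta=beta))

    f = n_with_motif / n_sites
    bayes = bayes_accuracy(
        f, rule.prob_methylated(True), rule.prob_methylated(False)
    )
    return SyntheticMethylome(
        genome=final, sites=sites, rule=rule, seed=seed, bayes_accuracy=bayes
    )


def bayes_accuracy(motif_fraction: float, p_hi: float, p_lo: float) -> float:
    """Best achievable label accuracy for the planted rule.

    The Bayes-optimal classifier observes motif presence only; with
    ``p_hi = P(beta >= 50 | motif)`` and ``p_lo = P(beta >= 50 | no motif)``
    its accuracy is the mixture of per-arm majority accuracies.  When
    ``p_hi == p_lo`` the rule is uninformative and this collapses to the
    majority-class base rate.
    """
    return motif_fraction * max(p_hi, 1 - p_hi) + (1 - motif_fraction) * max(
        p_lo, 1 - p_lo
    )


def methylated_fraction(sm: SyntheticMethylome) -> float:
    return sum(s.label == METHYLATED for s in sm.sites) / len(sm.sites)


def write_fixture(sm: SyntheticMethylome, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + methylation TSV (bed0 dialect) + JSON manifest.

    The files round-trip through the seqdata readers to the identical
    genome and site list.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    table = outdir / "methylation.tsv"
    manifest = outdir / "manifest.json"

    with open(fasta, "w") as fh:
        fh.write(f">{sm.genome.name}\n")
        for i in range(0, sm.genome.length, 70):
            fh.write(sm.genome.residues[i : i + 70] + "\n")
    write_methylation_table(sm.sites, table, dialect="bed0")
    with open(manifest, "w") as fh:
        json.dump(
            {
                "seed": sm.seed,
                "n_sites": len(sm.sites),
                "genome_name": sm.genome.name,
                "genome_length": sm.genome.length,
                "dialect": "bed0",
                "rule": asdict(sm.rule),
                "bayes_accuracy": sm.bayes_accuracy,
                "methylated_fraction": methylated_fraction(sm),
            },
            fh,
            indent=1,
        )
    return {"fasta": fasta, "table": table, "manifest": manifest}
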