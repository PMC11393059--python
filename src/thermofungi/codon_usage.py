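"""Codon-usage statistics: GC3/GC3s and Wright's effective number of codons.

Wright's ENC summarises how evenly a gene (or genome) uses synonymous
codons. For each amino acid with ``n >= 2`` codons observed, the
homozygosity estimate is

    F_hat = (n * sum(p_i^2) - 1) / (n - 1)

with ``p_i`` the within-family codon proportions. Averaging F_hat within
degeneracy classes (2-, 3-, 4-, 6-fold) gives class means ``F2..F6`` and

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

(the leading 2 accounts for Met and Trp, which admit no choice). ENC spans
20 (one codon per amino acid) to 61 (uniform synonymous usage); finite-data
estimates above 61 are clamped.

Group comparisons use the Wilcoxon rank-sum test and Mood's median test,
and the GC3-vs-ENC relationship is summarised by a Pearson correlation with
a grand-mean quadrant assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .formats_io import SequenceSet

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))

#: amino acid -> tuple of synonymous codons (sorted)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(aa, ())
    AA_TO_CODONS[aa] += (codon,)

CODON_TO_AA = dict(_TABLE.forward_table)

#: degeneracy class -> amino acids, used by the ENC class means
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for aa, codons in AA_TO_CODONS.items():
    DEGENERACY_CLASSES.setdefault(len(codons), ())
    DEGENERACY_CLASSES[len(codons)] += (aa,)

# class multiplicities in the ENC formula: 9 two-fold, 1 three-fold (Ile),
# 5 four-fold, 3 six-fold amino acids
_ENC_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCounts:
    """Codon counts for one gene (or a pool of genes)."""

    counts: dict[str, int] = field(default_factory=dict)
    stop_count: int = 0
    skipped_codons: int = 0  # codons containing N
    status: str = "ok"  # ok | internal_stop | bad_length

    def total_sense(self) -> int:
        return sum(self.counts.values())

    def scaled(self, factor: int) -> "CodonCounts":
        return CodonCounts(
            counts={c: n * factor for c, n in self.counts.items()},
            stop_count=self.stop_count * factor,
        )

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for c, n in other.counts.items():
            merged[c] = merged.get(c, 0) + n
        return CodonCounts(
            counts=merged,
            stop_count=self.stop_count + other.stop_count,
            skipped_codons=self.skipped_codons + other.skipped_codons,
        )


def count_codons(cds: str) -> CodonCounts:
    """Count sense codons of one coding sequence.

    A terminal stop codon is trimmed and tallied separately. A length not
    divisible by 3 or an internal stop marks the gene as unusable (status
    ``bad_length`` / ``internal_stop``) rather than raising: such genes are
    reported and skipped by :func:`genome_profile`. Codons containing N are
    excluded and counted as skipped.
    """
    seq = cds.upper()
    out = CodonCounts()
    if len(seq) % 3 != 0:
        out.status = "bad_length"
        return out
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        out.stop_count += 1
        codons = codons[:-1]
    for codon in codons:
        if "N" in codon:
            out.skipped_codons += 1
        elif codon in STOP_CODONS:
            out.status = "internal_stop"
            return out
        else:
            out.counts[codon] = out.counts.get(codon, 0) + 1
    return out


def gc3(counts: CodonCounts) -> float:
    """Fraction of G/C at the third position over all sense codons."""
    total = counts.total_sense()
    if total == 0:
        return math.nan
    gc = sum(n for c, n in counts.counts.items() if c[2] in "GC")
    return gc / total


def gc3s(counts: CodonCounts) -> float:
    """GC3 over synonymous families only (Met, Trp and stops excluded)."""
    total = gc = 0
    for codon, n in counts.counts.items():
        if len(AA_TO_CODONS[CODON_TO_AA[codon]]) == 1:
            continue
        total += n
        if codon[2] in "GC":
            gc += n
    return gc / total if total else math.nan


@dataclass
class EncComponents:
    """Intermediates of Wright's estimator: per-amino-acid F_hat and class means."""

    f_hat: dict[str, float]
    class_means: dict[int, float]
    enc_raw: float  # pre-clamp
    enc: float  # clamped to [., 61]; NaN when non-computable
    f3_fallback_used: bool = False


def enc_components(counts: CodonCounts) -> EncComponents:
    """Wright's ENC with CodonW-style fallbacks.

    Amino acids with fewer than 2 observed codons contribute nothing to
    their class mean. A non-computable 3-fold mean (Ile unobserved) is
    replaced by ``(F2 + F4)/2``; a non-computable 2-, 4- or 6-fold mean
    makes ENC missing (NaN).
    """
    f_hat: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) == 1:
            continue
        ns = np.array([counts.counts.get(c, 0) for c in codons], dtype=float)
        n = ns.sum()
        if n < 2:
            continue
        p = ns / n
        f = (n * (p ** 2).sum() - 1.0) / (n - 1.0)
        f_hat[aa] = float(f)

    class_means: dict[int, float] = {}
    for s, aas in sorted(DEGENERACY_CLASSES.items()):
        if s == 1:
            continue
        vals = [f_hat[aa] for aa in aas if aa in f_hat]
        if vals:
            class_means[s] = float(np.mean(vals))

    fallback = False
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
        fallback = True

    if any(s not in class_means or class_means[s] <= 0 for s in (2, 3, 4, 6)):
        return EncComponents(f_hat, class_means, math.nan, math.nan, fallback)

    raw = 2.0 + sum(w / class_means[s] for s, w in _ENC_WEIGHTS.items())
    return EncComponents(f_hat, class_means, raw, min(raw, 61.0), fallback)


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons, clamped at 61; NaN if missing."""
    return enc_components(counts).enc


# ---------------------------------------------------------------------------
# per-gene and per-genome profiles
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageRecord:
    gene: str
    gc3: float
    gc3s: float
    enc: float
    enc_raw: float
    status: str


def genome_profile(seqs: SequenceSet) -> tuple[pd.DataFrame, dict]:
    """Per-gene codon-usage records plus genome-level aggregates.

    Returns ``(per_gene, aggregate)`` where ``aggregate`` reports both the
    mean over usable genes and the pooled-count variant of each statistic,
    along with a tally of skipped genes.
    """
    records: list[CodonUsageRecord] = []
    pooled = CodonCounts()
    skipped = {"bad_length": 0, "internal_stop": 0}
    for gene, seq in seqs.records.items():
        cc = count_codons(seq)
        if cc.status != "ok":
            skipped[cc.status] += 1
            logger.warning("genome_profile: gene %s skipped (%s)", gene, cc.status)
            records.append(
                CodonUsageRecord(gene, math.nan, math.nan, math.nan, math.nan, cc.status)
            )
            continue
        comp = enc_components(cc)
        records.append(
            CodonUsageRecord(gene, gc3(cc), gc3s(cc), comp.enc, comp.enc_raw, "ok")
        )
        pooled = pooled + cc
    per_gene = pd.DataFrame([r.__dict__ for r in records]).set_index("gene")
    usable = per_gene[per_gene["status"] == "ok"]
    if usable.empty:
        raise ValueError("all genes skipped; no usable coding sequence")
    pooled_comp = enc_components(pooled)
    aggregate = {
        "n_genes": len(per_gene),
        "n_usable": len(usable),
        "n_skipped_bad_length": skipped["bad_length"],
        "n_skipped_internal_stop": skipped["internal_stop"],
        "mean_gc3": float(usable["gc3"].mean()),
        "mean_gc3s": float(usable["gc3s"].mean()),
        "mean_enc": float(usable["enc"].mean()),
        "pooled_gc3": gc3(pooled),
        "pooled_gc3s": gc3s(pooled),
        "pooled_enc": pooled_comp.enc,
    }
    return per_gene, aggregate


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str
    groups: tuple[str, str]
    statistic: float
    p_value: float
    medians: tuple[float, float]
    means: tuple[float, float]


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p: exact when both n <= 20 with no ties, else the
    tie-corrected normal approximation (no continuity correction)."""
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 20 and len(y) <= 20 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def _moods_median(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mood's median test: 2x2 table of above/below the grand median (values
    equal to it excluded); exact Fisher p for small expected counts, else
    chi-square without continuity correction."""
    grand = float(np.median(np.concatenate([x, y])))
    a, b = int((x > grand).sum()), int((x < grand).sum())
    c, d = int((y > grand).sum()), int((y < grand).sum())
    table = np.array([[a, c], [b, d]], dtype=float)
    if table.sum() == 0:
        return math.nan, 1.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return math.nan, float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_lifestyles(
    values_by_group: dict[str, "np.ndarray | list[float]"],
    test: str = "wilcoxon_rank_sum",
) -> GroupComparison:
    """Two-group location comparison (Wilcoxon rank-sum or Mood's median)."""
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups are required")
    (ga, xa), (gb, xb) = values_by_group.items()
    x = np.asarray(xa, dtype=float)
    y = np.asarray(xb, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "wilcoxon_rank_sum":
        stat, p = _wilcoxon_rank_sum(x, y)
    elif test == "moods_median":
        stat, p = _moods_median(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        test=test,
        groups=(ga, gb),
        statistic=stat,
        p_value=p,
        medians=(float(np.median(x)), float(np.median(y))),
        means=(float(np.mean(x)), float(np.mean(y))),
    )


# ---------------------------------------------------------------------------
# correlation and quadrants
# ---------------------------------------------------------------------------

def correlation_and_quadrants(
    aggregates: pd.DataFrame,
    x: str = "gc3",
    y: str = "enc",
    lifestyle_col: str = "lifestyle",
) -> dict:
    """Pearson r (and r^2) between per-genome GC3 and ENC plus quadrant labels.

    Quadrants are split at the grand means; Q1 is the high-GC3 / low-ENC
    quadrant (where thermophiles concentrate), Q2 high/high, Q3 low/high,
    Q4 low/low. Genomes lying exactly on a mean are labelled ``boundary``.
    """
    if len(aggregates) < 3:
        raise ValueError("need at least 3 genomes")
    xs = aggregates[x].to_numpy(dtype=float)
    ys = aggregates[y].to_numpy(dtype=float)
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(xs, ys)
    mx, my = float(np.mean(xs)), float(np.mean(ys))

    def quadrant(xv: float, yv: float) -> str:
        if xv == mx or yv == my:
            return "boundary"
        if xv > mx:
            return "Q1" if yv < my else "Q2"
        return "Q4" if yv < my else "Q3"

    labels = pd.Series(
        [quadrant(a, b) for a, b in zip(xs, ys)], index=aggregates.index,
        name="quadrant",
    )
    out = {
        "r": float(r),
        "r2": float(r) ** 2,
        "p_value": float(p),
        "mean_x": mx,
        "mean_y": my,
        "quadrants": labels,
    }
    if lifestyle_col in aggregates.columns:
        frac = (
            pd.crosstab(aggregates[lifestyle_col], labels, normalize="index")
            .reindex(columns=["Q1", "Q2", "Q3", "Q4", "boundary"], fill_value=0.0)
        )
        out["lifestyle_quadrant_fractions"] = frac
    return out


def uniform_codon_counts(per_codon: int = 10_000) -> CodonCounts:
    """Counts with every synonymous codon used equally (the no-bias pole)."""
    return CodonCounts(counts={c: per_codon for c in SENSE_CODONS})


def single_codon_counts(per_aa: int = 10_000) -> CodonCounts:
    """Counts with exactly one codon per amino acid (the maximal-bias pole)."""
    return CodonCounts(
        counts={codons[0]: per_aa for codons in AA_TO_CODONS.values()}
    )
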