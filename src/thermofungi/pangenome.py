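"""Core/shell/unique pangenome partitioning and rarefaction curves.

For a set of genomes, an orthogroup is *core* when present in every genome
of the set, *unique* when present in exactly one, and *shell* when present
in two or more but not all. For a single-genome set every present
orthogroup is core (core takes precedence over unique when the definitions
coincide). Rarefaction curves report the mean and standard deviation of
each category size over repeated uniform subsampling without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import OrthogroupMatrix

logger = logging.getLogger(__name__)


@dataclass
class PangenomePartition:
    genome_set: tuple[str, ...]
    core: frozenset[str]
    shell: frozenset[str]
    unique: frozenset[str]

    @property
    def pangenome(self) -> frozenset[str]:
        return self.core | self.shell | self.unique

    def sizes(self) -> dict[str, int]:
        return {
            "core": len(self.core),
            "shell": len(self.shell),
            "unique": len(self.unique),
            "pangenome": len(self.pangenome),
        }


def classify(matrix: OrthogroupMatrix, genome_set: "list[str] | tuple[str, ...]") -> PangenomePartition:
    """Partition the orthogroups present in ``genome_set`` into core/shell/unique."""
    genomes = tuple(sorted(genome_set))
    if not genomes:
        raise ValueError("genome_set is empty")
    missing = set(genomes) - set(matrix.genomes)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    pres = matrix.presence()[list(genomes)]
    n_present = pres.sum(axis=1)
    total = len(genomes)
    core = frozenset(pres.index[n_present == total])
    if total == 1:
        # precedence: a single-genome "core" swallows the unique definition
        return PangenomePartition(genomes, core, frozenset(), frozenset())
    unique = frozenset(pres.index[n_present == 1])
    shell = frozenset(pres.index[(n_present >= 2) & (n_present < total)])
    return PangenomePartition(genomes, core, shell, unique)


def rarefy(
    matrix: OrthogroupMatrix,
    genome_set: "list[str] | tuple[str, ...]",
    R: int = 100,
    seed: "int | None" = None,
) -> pd.DataFrame:
    """Rarefaction curve: for each subsample size ``n`` draw ``R`` uniform
    subsets without replacement and report mean and SD of each category size.

    ``n == |genome_set|`` short-circuits to the exact partition with SD 0.
    Returns a tidy frame with columns n, statistic, mean, sd.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible rarefaction")
    if R < 1:
        raise ValueError("R must be >= 1")
    genomes = sorted(genome_set)
    rng = np.random.default_rng(seed)
    logger.info(
        "rarefy: %d genomes, R=%d, seed=%d", len(genomes), R, seed
    )
    rows = []
    for n in range(1, len(genomes) + 1):
        if n == len(genomes):
            sizes = pd.DataFrame([classify(matrix, genomes).sizes()])
        else:
            draws = [
                classify(matrix, list(rng.choice(genomes, size=n, replace=False))).sizes()
                for _ in range(R)
            ]
            sizes = pd.DataFrame(draws)
        for stat in ("core", "shell", "unique", "pangenome"):
            rows.append(
                {
                    "n": n,
                    "statistic": stat,
                    "mean": float(sizes[stat].mean()),
                    "sd": float(sizes[stat].std(ddof=0)) if len(sizes) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonSummary:
    partition_a: PangenomePartition
    partition_b: PangenomePartition
    curve_a: pd.DataFrame
    curve_b: pd.DataFrame
    lost_core_a_vs_b: frozenset[str]  # core(b) \ core(a): lost from a's core
    lost_core_b_vs_a: frozenset[str]

    def sizes(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.partition_a.sizes(), self.partition_b.sizes()],
            index=["group_a", "group_b"],
        )


def compare_groups(
    matrix: OrthogroupMatrix,
    group_a: "list[str]",
    group_b: "list[str]",
    R: int = 100,
    seed: "int | None" = None,
) -> GroupComparisonSummary:
    """Side-by-side partitions and rarefaction curves for two disjoint groups.

    ``lost_core_a_vs_b`` (core of b minus core of a) feeds the GO-loss
    enrichment of orthogroups missing from a reduced core.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    pa = classify(matrix, group_a)
    pb = classify(matrix, group_b)
    ca = rarefy(matrix, group_a, R=R, seed=seed)
    cb = rarefy(matrix, group_b, R=R, seed=None if seed is None else seed + 1)
    return GroupComparisonSummary(
        partition_a=pa,
        partition_b=pb,
        curve_a=ca,
        curve_b=cb,
        lost_core_a_vs_b=frozenset(pb.core - pa.core),
        lost_core_b_vs_a=frozenset(pa.core - pb.core),
    )
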