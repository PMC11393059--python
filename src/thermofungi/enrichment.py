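"""GO-term enrichment of orthogroups lost from a reduced core genome.

One two-tailed Fisher's exact test per GO term over a 2x2 table of
lost/retained x annotated/not-annotated orthogroups, with Benjamini-
Hochberg control of the false discovery rate across terms. The default
universe is the reference (e.g. mesophile) core; the lost set is the part
of that core absent from the reduced (e.g. thermophile) core.

No GO-graph propagation is performed: a term annotates exactly the
orthogroups listed for it (ancestor propagation is a possible extension).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_GO_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class AnnotationTable:
    """Orthogroup id -> set of GO term ids, with optional term names."""

    annotations: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.annotations.values():
            out |= t
        return out


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a long-format TSV: orthogroup, go_term[, term_name] per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"annotation table {path} needs >= 2 columns")
    annotations: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        og, term = row[0], row[1]
        if not _GO_RE.match(term):
            raise ValueError(
                f"malformed GO id {term!r} at data row {i} of {path}"
            )
        annotations.setdefault(og, set()).add(term)
        if len(cols) >= 3 and isinstance(row[2], str):
            names[term] = row[2]
    logger.info(
        "read_annotations: %d orthogroups, %d terms from %s",
        len(annotations), len({t for s in annotations.values() for t in s}), path,
    )
    return AnnotationTable(
        annotations={k: frozenset(v) for k, v in annotations.items()},
        term_names=names,
    )


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed Fisher's exact test on the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``; p sums the hypergeometric probabilities of
    all tables (margins fixed) no more probable than the observed one. The
    odds ratio is a*d / (b*c), infinite when b*c = 0 with a*d > 0 and NaN
    for 0/0.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("negative cell in contingency table")
    if sum(cells) == 0:
        raise ValueError("all margins are zero")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    return float(odds), float(p)


def bh_adjust(p_values: "list[float] | np.ndarray") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def lost_core_enrichment(
    core_lost_set: "set[str] | frozenset[str]",
    universe_set: "set[str] | frozenset[str]",
    annotations: AnnotationTable,
    alpha: float = 0.05,
    significant_only: bool = False,
) -> pd.DataFrame:
    """Term-by-term enrichment of the lost-core set within the universe.

    Tests every GO term annotating at least one universe member; results
    are sorted by adjusted p and carry a ``log10_p_adj`` column matching
    the usual enrichment-plot axis.
    """
    lost = set(core_lost_set)
    universe = set(universe_set)
    if not universe:
        raise ValueError("empty universe")
    if not lost <= universe:
        raise ValueError("lost set must be a subset of the universe")
    retained = universe - lost

    term_members: dict[str, set[str]] = {}
    for og in universe:
        for term in annotations.annotations.get(og, ()):
            term_members.setdefault(term, set()).add(og)

    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        a = len(members & lost)
        b = len(lost) - a
        c = len(members & retained)
        d = len(retained) - c
        odds, p = fisher_two_tailed(a, b, c, d)
        rows.append(
            {
                "term": term,
                "name": annotations.term_names.get(term, ""),
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "a", "b", "c", "d", "odds_ratio", "p",
                     "p_adj", "log10_p_adj", "significant"]
        )
    result = pd.DataFrame(rows)
    result["p_adj"] = bh_adjust(result["p"].to_numpy())
    with np.errstate(divide="ignore"):
        result["log10_p_adj"] = np.log10(result["p_adj"])
    result["significant"] = result["p_adj"] <= alpha
    result = result.sort_values(
        ["p_adj", "p", "term"], kind="mergesort"
    ).reset_index(drop=True)
    if significant_only:
        result = result[result["significant"]].reset_index(drop=True)
    logger.info(
        "lost_core_enrichment: %d terms tested, %d significant at %.3g",
        len(result), int(result["significant"].sum()) if len(result) else 0, alpha,
    )
    return result
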