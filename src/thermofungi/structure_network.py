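"""Structural-similarity network of predicted protein structures.

Edges join structure pairs whose fraction of identical aligned residues
(fident) and TM-score both exceed their thresholds (defaults 0.7 and 0.8,
strict); clusters are the connected components. Disulfide bonds are counted
from cysteine SG-SG distances, and per-cluster summaries overlay lifestyle,
disulfide counts, and optimal-temperature annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .formats_io import PairwiseScoreTable, StructureModel

logger = logging.getLogger(__name__)


def build_graph(
    table: PairwiseScoreTable,
    fident_min: float = 0.7,
    tm_min: float = 0.8,
) -> nx.Graph:
    """Threshold a pairwise score table into an undirected similarity graph.

    Asymmetric duplicates (a->b and b->a) are merged per score by maximum
    before thresholding; an edge survives iff fident > fident_min AND
    tmscore > tm_min. Every structure mentioned in the table stays in the
    graph, isolated or not.
    """
    g = nx.Graph()
    best: dict[tuple[str, str], list[float]] = {}
    for row in table.scores.itertuples(index=False):
        g.add_node(row.query)
        g.add_node(row.target)
        key = (row.query, row.target) if row.query <= row.target else (row.target, row.query)
        cur = best.setdefault(key, [0.0, 0.0])
        cur[0] = max(cur[0], row.fident)
        cur[1] = max(cur[1], row.tmscore)
    kept = 0
    for (u, v), (fid, tm) in best.items():
        if fid > fident_min and tm > tm_min:
            g.add_edge(u, v, fident=fid, tmscore=tm)
            kept += 1
    logger.info(
        "build_graph: %d nodes, %d/%d merged pairs kept (fident>%.2f, tm>%.2f)",
        g.number_of_nodes(), kept, len(best), fident_min, tm_min,
    )
    return g


@dataclass
class ClusterAssignment:
    """Structure id -> 1-based cluster label, largest cluster first."""

    labels: dict[str, int]
    sizes: list[int]
    flags: dict[int, str] = field(default_factory=dict)  # duplet/triplet

    def members(self, label: int) -> list[str]:
        return sorted(s for s, l in self.labels.items() if l == label)


def cluster(graph: nx.Graph) -> ClusterAssignment:
    """Connected components, labelled by descending size (ties: smallest
    member id); 2- and 3-member components are flagged duplet/triplet."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    labels: dict[str, int] = {}
    sizes: list[int] = []
    flags: dict[int, str] = {}
    for i, comp in enumerate(comps, start=1):
        for node in comp:
            labels[node] = i
        sizes.append(len(comp))
        if len(comp) == 2:
            flags[i] = "duplet"
        elif len(comp) == 3:
            flags[i] = "triplet"
    logger.info("cluster: %d components, sizes %s", len(sizes), sizes[:10])
    return ClusterAssignment(labels=labels, sizes=sizes, flags=flags)


def count_disulfides(
    structure: StructureModel, max_dist: float = 2.5
) -> tuple[int, list[tuple[int, int]]]:
    """Count disulfide bonds from CYS SG-SG geometry.

    Candidate pairs are SG atoms of distinct cysteines within ``max_dist``
    angstroms (true S-S bonds sit near 2.05 A; the default leaves slack for
    model error). Greedy matching by ascending distance ensures each
    cysteine joins at most one bond. Returns (count, residue-index pairs).
    """
    atoms = structure.atoms
    cys = atoms[atoms["residue_name"] == "CYS"]
    sg = cys[cys["atom_name"] == "SG"]
    no_sg = set(cys["residue_index"]) - set(sg["residue_index"])
    for resi in sorted(no_sg):
        logger.warning(
            "count_disulfides: CYS %d in %s lacks an SG atom, skipped",
            resi, structure.name,
        )
    idx = sg["residue_index"].to_numpy()
    xyz = sg[["x", "y", "z"]].to_numpy(dtype=float)
    candidates = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            if idx[i] == idx[j]:
                continue
            dist = float(np.linalg.norm(xyz[i] - xyz[j]))
            if dist <= max_dist:
                candidates.append((dist, int(idx[i]), int(idx[j])))
    candidates.sort()
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, ri, rj in candidates:
        if ri in used or rj in used:
            continue
        used.update((ri, rj))
        pairs.append((min(ri, rj), max(ri, rj)))
    return len(pairs), sorted(pairs)


def annotate_and_summarize(
    assignment: ClusterAssignment,
    metadata: "pd.DataFrame | None" = None,
    temp_band: tuple[float, float] = (55.0, 60.0),
) -> dict:
    """Per-cluster composition summary with optional temperature overlay.

    ``metadata`` is indexed by structure id with optional columns
    ``lifestyle``, ``disulfides`` and ``optimal_temp_c`` (missing values
    allowed). Reports per cluster: size, duplet/triplet flag, lifestyle
    composition, disulfide-count values with a constant-within-cluster
    flag, and membership of the ``temp_band`` (inclusive). Globally:
    the fraction of band members falling in their modal cluster and the
    percentage of structures with a temperature annotation.
    """
    meta = metadata if metadata is not None else pd.DataFrame(
        index=pd.Index(sorted(assignment.labels), name="structure")
    )
    rows = []
    band_clusters: list[int] = []
    lo, hi = temp_band
    has_temp = "optimal_temp_c" in meta.columns
    for label in range(1, len(assignment.sizes) + 1):
        members = assignment.members(label)
        row: dict = {
            "cluster": label,
            "size": len(members),
            "flag": assignment.flags.get(label, ""),
        }
        if "lifestyle" in meta.columns:
            comp = meta.reindex(members)["lifestyle"].value_counts().to_dict()
            row["lifestyles"] = ";".join(f"{k}={v}" for k, v in sorted(comp.items()))
        if "disulfides" in meta.columns:
            vals = meta.reindex(members)["disulfides"].dropna()
            row["disulfide_values"] = ";".join(str(int(v)) for v in sorted(vals.unique()))
            row["disulfides_constant"] = bool(vals.nunique() <= 1)
        if has_temp:
            temps = meta.reindex(members)["optimal_temp_c"].dropna()
            in_band = temps[(temps >= lo) & (temps <= hi)]
            row["n_temp_annotated"] = int(len(temps))
            row["n_in_band"] = int(len(in_band))
            band_clusters.extend([label] * len(in_band))
        rows.append(row)
    summary = {"clusters": pd.DataFrame(rows)}
    if has_temp:
        n_annotated = int(meta["optimal_temp_c"].notna().sum())
        summary["temperature_coverage_pct"] = 100.0 * n_annotated / len(meta)
        if band_clusters:
            counts = pd.Series(band_clusters).value_counts()
            summary["band_modal_cluster"] = int(counts.index[0])
            summary["band_fraction_in_modal_cluster"] = float(
                counts.iloc[0] / counts.sum()
            )
    return summary


def export_graph(graph: nx.Graph, edges_path, gml_path=None) -> None:
    """Write the edge list as TSV (and optionally GML for external viewers)."""
    rows = [
        {"source": u, "target": v, "fident": d["fident"], "tmscore": d["tmscore"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "fident", "tmscore"]).to_csv(
        edges_path, sep="\t", index=False, float_format="%.6f"
    )
    if gml_path is not None:
        nx.write_gml(graph, gml_path)
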