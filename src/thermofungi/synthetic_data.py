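"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of a thermophile /
mesophile comparative-genomics study: a genome panel with lifestyle labels
(defaults 29 thermophiles, 8 thermotolerant, 42 mesophiles), an orthogroup
count matrix with a planted core-genome reduction in thermophiles and a
small set of lifestyle-discriminative orthogroups, coding sequences with
tunable third-position GC and codon bias, a species tree with tip states
evolved under the Mk1 model, toy PDB structures with planted disulfide
bonds, and a pairwise structural-score table with planted clusters.

Everything is deterministic given the spec seed: each generator derives an
independent RNG stream from ``(seed, stage-tag)``, so stages compose
reproducibly and a re-run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import codon_usage as cu
from .ancestral_state import mk1_transition
from .formats_io import (
    OrthogroupMatrix,
    PairwiseScoreTable,
    Phylogeny,
    SequenceSet,
    StructureModel,
    write_count_matrix,
    write_fasta,
    write_foldseek_tsv,
    write_metadata,
    write_newick,
    write_pdb,
)

logger = logging.getLogger(__name__)

# stage tags for independent RNG streams
_STREAMS = {
    "genomes": 1, "hogs": 2, "cds": 3, "tree": 4, "pdb": 5, "scores": 6,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stage]])


@dataclass
class SyntheticSpec:
    """Study conditions for the generators.

    Defaults mirror the design the pipeline targets: 29/8/42 genomes, a
    thermophile core visibly smaller than the mesophile core, eight planted
    discriminative orthogroups whose presence splits the classes roughly
    9:1, moderate codon bias with a thermophile GC3 shift, and a single
    symmetric lifestyle-transition rate on the tree.
    """

    n_thermophile: int = 29
    n_mesophile: int = 42
    n_thermotolerant: int = 8
    core_size_by_lifestyle: dict = field(
        default_factory=lambda: {
            "thermophilic": 120, "mesophilic": 200, "thermotolerant": 180,
        }
    )
    n_accessory: int = 500
    n_orthogroups: "int | None" = None  # None = sized automatically
    shell_rate: float = 0.25
    unique_rate: float = 0.4
    n_discriminative: int = 8
    exception_rate: float = 0.17  # fraction of labeled genomes with flipped
    # discriminative profiles; flips cover half the features per exception
    # genome (a fixed pair-covering design when n_discriminative = 8) so the
    # planted features complement one another
    n_genes: int = 60
    len_codons: int = 200
    gc3_target: float = 0.52
    bias_strength: float = 0.3
    gc3_shift_thermophile: float = 0.08
    bias_shift_thermophile: float = 0.15
    mk1_rate: float = 0.5
    k_states: int = 3
    branch_scale: float = 0.3
    n_structures: int = 24
    structure_cluster_sizes: tuple = (10, 6, 4, 2, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_thermophile, self.n_mesophile, self.n_thermotolerant)
        if any(c < 0 for c in counts):
            raise ValueError("genome counts must be >= 0")
        for p in (self.shell_rate, self.unique_rate, self.bias_strength):
            if not 0 <= p <= 1:
                raise ValueError("rates/probabilities must lie in [0, 1]")
        if not 0 <= self.gc3_target <= 1:
            raise ValueError("gc3_target must lie in [0, 1]")
        if self.mk1_rate < 0:
            raise ValueError("mk1_rate must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    core_by_lifestyle: dict = field(default_factory=dict)
    lost_core_thermophile: list = field(default_factory=list)
    discriminative: list = field(default_factory=list)
    discriminative_favored: dict = field(default_factory=dict)
    exception_genomes: list = field(default_factory=list)
    disulfide_pairs: dict = field(default_factory=dict)
    structure_clusters: dict = field(default_factory=dict)
    ancestral_states: dict = field(default_factory=dict)
    tip_states: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# genomes and orthogroup counts
# ---------------------------------------------------------------------------

def gen_genome_set(spec: SyntheticSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Genome metadata table with exact lifestyle proportions."""
    total = spec.n_thermophile + spec.n_mesophile + spec.n_thermotolerant
    if total == 0:
        raise ValueError("at least one genome is required")
    if spec.n_thermophile < 1 or spec.n_mesophile < 1:
        raise ValueError("need >= 1 thermophile and >= 1 mesophile")
    rng = _rng(spec.seed, "genomes")
    rows = []
    size_ranges = {
        "thermophilic": (24.0, 34.0),
        "mesophilic": (34.0, 50.0),
        "thermotolerant": (30.0, 42.0),
    }
    for prefix, lifestyle, n in (
        ("thermo", "thermophilic", spec.n_thermophile),
        ("meso", "mesophilic", spec.n_mesophile),
        ("ttol", "thermotolerant", spec.n_thermotolerant),
    ):
        lo, hi = size_ranges[lifestyle]
        for i in range(n):
            rows.append(
                {
                    "genome": f"{prefix}_{i + 1:02d}",
                    "lifestyle": lifestyle,
                    "clade": "cladeA" if i % 2 == 0 else "cladeB",
                    "assembly_size_mbp": round(float(rng.uniform(lo, hi)), 2),
                }
            )
    meta = pd.DataFrame(rows).set_index("genome")
    logger.info("gen_genome_set: %d genomes (seed=%d)", total, spec.seed)
    return meta, GroundTruth()


# triple flip-blocks over 8 features covering every feature pair at least
# twice with near-balanced feature degrees: any two features are jointly
# flipped in >= 2 exception genomes, while three flips stay a minority in
# any combination of seven or more features
_TRIPLE_COVER_8 = (
    (2, 3, 7), (0, 4, 5), (1, 3, 4), (5, 6, 7), (0, 2, 6),
    (0, 1, 7), (1, 2, 5), (3, 4, 6), (0, 3, 5), (2, 4, 7),
    (1, 2, 6), (0, 1, 6), (3, 5, 7), (0, 2, 3), (1, 4, 5),
    (4, 6, 7), (3, 5, 6), (0, 4, 7), (2, 4, 5), (1, 3, 7),
)


def _exception_blocks(
    n_disc: int, rate: float, n_labeled: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Flip sets for the exception genomes (see gen_hog_matrix)."""
    if n_disc == 8:
        return list(_TRIPLE_COVER_8)
    n_exc = int(round(rate * n_labeled))
    size = max(1, min(n_disc - 1, (n_disc + 1) // 3))
    return [
        tuple(rng.choice(n_disc, size=size, replace=False)) for _ in range(n_exc)
    ]


def _avoid_full_groups(
    present: np.ndarray, group_indices: list[np.ndarray], rng: np.random.Generator
) -> None:
    """Knock one member out of any lifestyle group fully covered, in place,
    so that accessory/discriminative orthogroups never join a planted core."""
    for idx in group_indices:
        if len(idx) >= 2 and present[idx].all():
            present[rng.choice(idx)] = False


def gen_hog_matrix(
    spec: SyntheticSpec, meta: pd.DataFrame, truth: "GroundTruth | None" = None
) -> tuple[OrthogroupMatrix, GroundTruth]:
    """Orthogroup count matrix with planted cores and discriminative features.

    Lifestyle cores are nested: the largest requested core is a backbone of
    orthogroups present in every genome of that lifestyle, and each smaller
    core keeps a prefix of it; backbone orthogroups dropped from the
    thermophile core (the planted loss) appear only sporadically in
    thermophiles. Discriminative orthogroups are near-fixed in a favored
    class and near-absent in the other, with deviations concentrated in a
    few "exception" genomes so the features complement each other.
    Accessory orthogroups are unique or shell per the spec rates.
    """
    truth = truth if truth is not None else GroundTruth()
    rng = _rng(spec.seed, "hogs")
    genomes = list(meta.index)
    n_g = len(genomes)
    lifestyles = meta["lifestyle"]
    groups = {
        ls: np.flatnonzero((lifestyles == ls).to_numpy())
        for ls in lifestyles.unique()
    }
    core_sizes = {
        ls: s for ls, s in spec.core_size_by_lifestyle.items() if ls in groups
    }
    max_core = max(core_sizes.values(), default=0)
    n_total_needed = max_core + spec.n_discriminative + spec.n_accessory
    if spec.n_orthogroups is not None and n_total_needed > spec.n_orthogroups:
        raise ValueError(
            f"core sizes + discriminative + accessory = {n_total_needed} exceed "
            f"the orthogroup budget {spec.n_orthogroups}"
        )

    og_ids = [f"OG{i + 1:07d}" for i in range(n_total_needed)]
    presence = np.zeros((n_total_needed, n_g), dtype=bool)

    # nested lifestyle cores over the backbone block [0, max_core)
    for ls, idx in groups.items():
        size = core_sizes.get(ls, 0)
        presence[:size, idx] = True
        # beyond its core, a lifestyle sees backbone orthogroups in roughly
        # half its genomes: the loss is a core-membership loss, not a clean
        # absence, so these orthogroups separate the classes only weakly
        rest = np.arange(size, max_core)
        if len(rest):
            sporadic = rng.random((len(rest), len(idx))) < 0.5
            for r, row in zip(rest, sporadic):
                presence[r, idx] = row
    for r in range(max_core):
        _avoid_full_groups(presence[r], [
            idx for ls, idx in groups.items() if r >= core_sizes.get(ls, 0)
        ], rng)

    truth.core_by_lifestyle = {
        ls: og_ids[: core_sizes.get(ls, 0)] for ls in groups
    }
    thermo_sz = core_sizes.get("thermophilic", 0)
    meso_sz = core_sizes.get("mesophilic", 0)
    truth.lost_core_thermophile = og_ids[thermo_sz:meso_sz] if meso_sz > thermo_sz else []

    # discriminative block
    disc = np.arange(max_core, max_core + spec.n_discriminative)
    labeled_idx = np.concatenate(
        [groups.get("thermophilic", []), groups.get("mesophilic", [])]
    ).astype(int)
    favored_classes = {}
    for j, r in enumerate(disc):
        favored = "mesophilic" if j % 2 == 0 else "thermophilic"
        favored_classes[og_ids[r]] = favored
        fav_idx = groups[favored]
        presence[r, fav_idx] = True
        # thermotolerant genomes carry a mesophile-like profile
        if "thermotolerant" in groups:
            tt = groups["thermotolerant"]
            if favored == "mesophilic":
                presence[r, tt] = rng.random(len(tt)) >= 0.05
            else:
                presence[r, tt] = rng.random(len(tt)) < 0.05
    # exception genomes: each flips half the discriminative features to the
    # opposite pole. The flip sets form a (doubled) pair-covering design, so
    # every feature pair is jointly flipped in at least two genomes: no small
    # feature combination can classify perfectly, while in combinations of
    # six or more features the flipped half stays a minority vote. This is
    # what makes the planted features complementary rather than redundant.
    flip_blocks = _exception_blocks(spec.n_discriminative, spec.exception_rate,
                                    len(labeled_idx), rng)
    n_exc = min(len(flip_blocks), len(labeled_idx))
    exc_idx = rng.choice(labeled_idx, size=n_exc, replace=False) if n_exc else np.array([], dtype=int)
    for g, block in zip(exc_idx, flip_blocks):
        flipped = disc[list(block)]
        presence[flipped, g] = ~presence[flipped, g]
    for r in disc:
        _avoid_full_groups(presence[r], list(groups.values()), rng)
    truth.discriminative = [og_ids[r] for r in disc]
    truth.discriminative_favored = favored_classes
    truth.exception_genomes = sorted(genomes[g] for g in exc_idx)

    # accessory block: unique or shell
    acc_start = max_core + spec.n_discriminative
    for r in range(acc_start, n_total_needed):
        if rng.random() < spec.unique_rate:
            presence[r, rng.integers(n_g)] = True
        else:
            size = 2 + rng.binomial(max(n_g - 2, 0), spec.shell_rate)
            size = min(size, n_g)
            members = rng.choice(n_g, size=size, replace=False)
            presence[r, members] = True
            _avoid_full_groups(presence[r], list(groups.values()), rng)

    counts = np.where(presence, 1 + rng.poisson(0.8, size=presence.shape), 0)
    # discriminative features are single-copy gene losses: presence/absence
    # carries the whole signal, as for informative orthogroups in practice
    counts[disc] = presence[disc].astype(int)
    counts_df = pd.DataFrame(counts, index=og_ids, columns=genomes)
    counts_df.index.name = "orthogroup"
    matrix = OrthogroupMatrix(counts=counts_df, lifestyles=lifestyles)
    logger.info(
        "gen_hog_matrix: %d orthogroups x %d genomes, %d discriminative, "
        "%d exception genomes (seed=%d)",
        n_total_needed, n_g, spec.n_discriminative, n_exc, spec.seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# coding sequences
# ---------------------------------------------------------------------------

def _codon_distributions(gc3_target: float, bias_strength: float) -> dict[str, tuple]:
    """Per-amino-acid codon sampling distributions.

    Within each synonymous family, probabilities interpolate linearly
    between uniform (bias 0) and a point mass on one preferred codon
    (bias 1). Preferred codons are assigned greedily to GC- or AT-ending
    choices so the expected GC3s tracks ``gc3_target`` as closely as the
    bias level allows.
    """
    b = bias_strength
    fams = sorted(
        (aa, codons) for aa, codons in cu.AA_TO_CODONS.items() if len(codons) > 1
    )
    # running greedy choice of preferred-codon class
    achieved = 0.0
    weight = 1.0 / len(fams)
    dists: dict[str, tuple] = {}
    running = 0.0
    n_done = 0
    for aa, codons in fams:
        gc_cod = [c for c in codons if c[2] in "GC"]
        at_cod = [c for c in codons if c[2] not in "GC"]
        frac_gc = len(gc_cod) / len(codons)
        base_term = (1 - b) * frac_gc
        options = []
        if gc_cod:
            options.append((base_term + b, gc_cod[0]))
        if at_cod:
            options.append((base_term, at_cod[0]))
        # pick the option keeping the running mean closest to target
        best = min(
            options,
            key=lambda opt: abs((running + opt[0]) / (n_done + 1) - gc3_target),
        )
        running += best[0]
        n_done += 1
        preferred = best[1]
        probs = np.full(len(codons), (1 - b) / len(codons))
        probs[codons.index(preferred)] += b
        dists[aa] = (codons, probs)
    for aa, codons in cu.AA_TO_CODONS.items():
        if len(codons) == 1:
            dists[aa] = (codons, np.array([1.0]))
    return dists


def gen_cds(
    n_genes: int,
    len_codons: int,
    gc3_target: float,
    bias_strength: float,
    seed: int,
    id_prefix: str = "gene",
) -> SequenceSet:
    """Coding sequences with tunable codon bias and third-position GC.

    Each gene starts with ATG, contains ``len_codons - 1`` sense codons
    sampled from the per-amino-acid distributions (amino acids uniform over
    the 20), and ends with a TAA stop; there are no internal stops.
    """
    if len_codons < 10:
        raise ValueError("len_codons must be >= 10")
    if not 0 <= gc3_target <= 1 or not 0 <= bias_strength <= 1:
        raise ValueError("gc3_target and bias_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dists = _codon_distributions(gc3_target, bias_strength)
    aas = sorted(cu.AA_TO_CODONS)
    records: dict[str, str] = {}
    for g in range(n_genes):
        aa_draw = rng.choice(len(aas), size=len_codons - 1)
        codons = ["ATG"]
        for a in aa_draw:
            codon_list, probs = dists[aas[a]]
            codons.append(codon_list[rng.choice(len(codon_list), p=probs)])
        codons.append("TAA")
        records[f"{id_prefix}{g + 1:04d}"] = "".join(codons)
    return SequenceSet(records=records, alphabet="dna")


# ---------------------------------------------------------------------------
# tree with Mk1-evolved states
# ---------------------------------------------------------------------------

def gen_tree_with_states(
    n_tips: int,
    k_states: int,
    mk1_rate: float,
    seed: int,
    tip_labels: "list[str] | None" = None,
    branch_scale: float = 0.3,
) -> tuple[Phylogeny, dict[str, int], dict[str, int]]:
    """Random rooted binary tree plus tip/ancestor states under Mk1.

    Topology by uniform random sequential joins; branch lengths are
    exponential with mean ``branch_scale``. States evolve root-to-tip using
    the closed-form Mk1 transition probabilities (rate 0 leaves every node
    in the root state). Returns (tree, tip_states, ancestor_states) with
    internal nodes labelled N0, N1, ... in preorder.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    if mk1_rate < 0:
        raise ValueError("mk1_rate must be non-negative")
    rng = np.random.default_rng(seed)
    labels = tip_labels if tip_labels is not None else [f"t{i+1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("tip_labels length must equal n_tips")

    taxa = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        taxon = taxa.new_taxon(lab)
        node = dendropy.Node(taxon=taxon)
        node.edge.length = float(rng.exponential(branch_scale))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(branch_scale))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    root = nodes[0]
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    n_internal = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = f"N{n_internal}"
            n_internal += 1

    tip_states: dict[str, int] = {}
    anc_states: dict[str, int] = {}
    state_of: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = int(rng.integers(k_states))
        else:
            P = mk1_transition(mk1_rate, k_states, node.edge.length or 0.0)
            state = int(rng.choice(k_states, p=P[state_of[node.parent_node]]))
        state_of[node] = state
        if node.is_leaf():
            tip_states[node.taxon.label] = state
        else:
            anc_states[node.label] = state
    return Phylogeny(tree=tree), tip_states, anc_states


# ---------------------------------------------------------------------------
# toy structures and pairwise scores
# ---------------------------------------------------------------------------

def gen_toy_pdb(
    n_res: int,
    disulfide_pairs: "list[tuple[int, int]]",
    seed: int,
    name: str = "toy",
) -> StructureModel:
    """Single-chain poly-alanine CA trace with CYS pairs planted at 2.05 A.

    Each requested pair (1-based residue indices) becomes two cysteines
    whose SG atoms sit exactly 2.05 A apart; distinct pairs are offset so
    every other SG-SG distance exceeds 4 A.
    """
    flat = [r for pair in disulfide_pairs for r in pair]
    if len(flat) != len(set(flat)):
        raise ValueError("disulfide pairs share a residue")
    if any(not 1 <= r <= n_res for r in flat):
        raise ValueError("pair residue index outside 1..n_res")
    if any(a == b for a, b in disulfide_pairs):
        raise ValueError("a pair must reference two distinct residues")
    cys = set(flat)
    rows = []
    for i in range(1, n_res + 1):
        res = "CYS" if i in cys else "ALA"
        rows.append((i, res, "CA", 3.8 * i, 0.0, 0.0))
    for p, (a, b) in enumerate(sorted(tuple(sorted(pr)) for pr in disulfide_pairs)):
        mid_x = 3.8 * (a + b) / 2.0
        y = 10.0 * (p + 1)
        rows.append((a, "CYS", "SG", mid_x - 1.025, y, 0.0))
        rows.append((b, "CYS", "SG", mid_x + 1.025, y, 0.0))
    atoms = pd.DataFrame(
        rows, columns=["residue_index", "residue_name", "atom_name", "x", "y", "z"]
    ).sort_values(["residue_index", "atom_name"], kind="mergesort").reset_index(drop=True)
    return StructureModel(atoms=atoms, name=name)


def gen_pairwise_scores(
    cluster_assignment: dict[str, int],
    seed: int,
    intra_fident: tuple[float, float] = (0.75, 0.95),
    intra_tm: tuple[float, float] = (0.85, 0.98),
    inter_fident: tuple[float, float] = (0.1, 0.6),
    inter_tm: tuple[float, float] = (0.1, 0.7),
    fident_threshold: float = 0.7,
    tm_threshold: float = 0.8,
) -> PairwiseScoreTable:
    """All-vs-all score table whose thresholded graph recovers the clusters.

    Intra-cluster scores are drawn strictly above the thresholds and
    inter-cluster scores strictly below; both directions of each pair are
    emitted (the reverse slightly lower, as Foldseek's asymmetric output
    would be) plus self-pairs, which the reader drops.
    """
    if intra_fident[0] <= fident_threshold or intra_tm[0] <= tm_threshold:
        raise ValueError("intra-cluster bounds must exceed the thresholds")
    if inter_fident[1] >= fident_threshold or inter_tm[1] >= tm_threshold:
        raise ValueError("inter-cluster bounds must stay below the thresholds")
    rng = np.random.default_rng(seed)
    ids = sorted(cluster_assignment)
    rows = []
    for i, a in enumerate(ids):
        rows.append((a, a, 1.0, 1.0))
        for b in ids[i + 1:]:
            same = cluster_assignment[a] == cluster_assignment[b]
            fr = intra_fident if same else inter_fident
            tr = intra_tm if same else inter_tm
            fid = float(rng.uniform(*fr))
            tm = float(rng.uniform(*tr))
            rows.append((a, b, fid, tm))
            eps = float(rng.uniform(0.0, 0.004))
            rows.append((b, a, max(fr[0], fid - eps), max(tr[0], tm - eps)))
    df = pd.DataFrame(rows, columns=["query", "target", "fident", "tmscore"])
    df = df[df["query"] != df["target"]].reset_index(drop=True)
    return PairwiseScoreTable(scores=df)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input plus truth.json.

    Writes metadata.tsv, hog_counts.tsv, cds/<genome>.fasta, tree.nwk,
    states.tsv, structures/<id>.pdb, protein_meta.tsv, pairwise.tsv and
    truth.json under ``outdir``; byte-identical across runs with the same
    spec and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "cds").mkdir(exist_ok=True)
    (outdir / "structures").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    meta, truth = gen_genome_set(spec)
    matrix, truth = gen_hog_matrix(spec, meta, truth)
    paths["metadata"] = outdir / "metadata.tsv"
    write_metadata(meta, paths["metadata"])
    paths["hog_counts"] = outdir / "hog_counts.tsv"
    write_count_matrix(matrix, paths["hog_counts"])

    cds_rng = _rng(spec.seed, "cds")
    for genome, row in meta.iterrows():
        if row["lifestyle"] == "thermophilic":
            g = min(1.0, spec.gc3_target + spec.gc3_shift_thermophile)
            b = min(1.0, spec.bias_strength + spec.bias_shift_thermophile)
        elif row["lifestyle"] == "thermotolerant":
            g = min(1.0, spec.gc3_target + spec.gc3_shift_thermophile / 2)
            b = min(1.0, spec.bias_strength + spec.bias_shift_thermophile / 2)
        else:
            g, b = spec.gc3_target, spec.bias_strength
        seqs = gen_cds(
            spec.n_genes, spec.len_codons, g, b,
            seed=int(cds_rng.integers(2**31)), id_prefix=f"{genome}_g",
        )
        write_fasta(seqs, outdir / "cds" / f"{genome}.fasta")
    paths["cds_dir"] = outdir / "cds"

    tree_rng = _rng(spec.seed, "tree")
    phy, tip_states, anc_states = gen_tree_with_states(
        n_tips=len(meta),
        k_states=spec.k_states,
        mk1_rate=spec.mk1_rate,
        seed=int(tree_rng.integers(2**31)),
        tip_labels=list(meta.index),
        branch_scale=spec.branch_scale,
    )
    truth.tip_states = tip_states
    truth.ancestral_states = anc_states
    paths["tree"] = outdir / "tree.nwk"
    write_newick(phy, paths["tree"])
    state_names = ("mesophilic", "thermophilic", "thermotolerant")[: spec.k_states]
    states_df = pd.DataFrame(
        {"tip": list(tip_states), "state": [state_names[s] for s in tip_states.values()]}
    )
    paths["states"] = outdir / "states.tsv"
    states_df.to_csv(paths["states"], sep="\t", index=False)

    pdb_rng = _rng(spec.seed, "pdb")
    cluster_assignment: dict[str, int] = {}
    disulfide_per_cluster: dict[int, int] = {}
    sid = 0
    for c, size in enumerate(spec.structure_cluster_sizes, start=1):
        disulfide_per_cluster[c] = c - 1  # constant within, distinct between
        for _ in range(size):
            sid += 1
            cluster_assignment[f"prot{sid:03d}"] = c
    protein_rows = []
    lifestyles = ("thermophilic", "mesophilic", "thermotolerant")
    for name, c in cluster_assignment.items():
        n_bonds = disulfide_per_cluster[c]
        pairs = [(2 * i + 1, 2 * i + 2) for i in range(n_bonds)]
        structure = gen_toy_pdb(
            n_res=30, disulfide_pairs=pairs,
            seed=int(pdb_rng.integers(2**31)), name=name,
        )
        write_pdb(structure, outdir / "structures" / f"{name}.pdb")
        truth.disulfide_pairs[name] = pairs
        # temperature annotation: sparse, with the 55-60 C band concentrated
        # in the largest cluster
        if c == 1 and len(protein_rows) % 2 == 0:
            temp = round(float(pdb_rng.uniform(55, 60)), 1)
        elif pdb_rng.random() < 0.2:
            temp = round(float(pdb_rng.uniform(30, 54)), 1)
        else:
            temp = None
        protein_rows.append(
            {
                "structure": name,
                "lifestyle": lifestyles[int(pdb_rng.integers(len(lifestyles)))],
                "optimal_temp_c": temp,
            }
        )
    truth.structure_clusters = cluster_assignment
    paths["structures_dir"] = outdir / "structures"
    paths["protein_meta"] = outdir / "protein_meta.tsv"
    pd.DataFrame(protein_rows).to_csv(
        paths["protein_meta"], sep="\t", index=False, float_format="%.1f"
    )

    scores_rng = _rng(spec.seed, "scores")
    table = gen_pairwise_scores(
        cluster_assignment, seed=int(scores_rng.integers(2**31))
    )
    paths["pairwise"] = outdir / "pairwise.tsv"
    write_foldseek_tsv(table, paths["pairwise"])

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    logger.info("simulate: wrote dataset to %s (seed=%d)", outdir, spec.seed)
    return paths


def validate_ground_truth(outdir: str | Path) -> None:
    """Check that every planted id in truth.json resolves in the artifacts."""
    outdir = Path(outdir)
    truth = json.loads((outdir / "truth.json").read_text())
    from .formats_io import read_count_matrix, read_metadata, read_newick

    matrix = read_count_matrix(outdir / "hog_counts.tsv")
    meta = read_metadata(outdir / "metadata.tsv")
    ogs = set(matrix.orthogroups)
    for ls, core in truth["core_by_lifestyle"].items():
        assert set(core) <= ogs, f"core ids for {ls} missing from matrix"
    assert set(truth["discriminative"]) <= ogs
    assert set(truth["exception_genomes"]) <= set(meta.index)
    phy = read_newick(outdir / "tree.nwk")
    assert set(truth["tip_states"]) == set(phy.tip_labels)
    for name in truth["structure_clusters"]:
        assert (outdir / "structures" / f"{name}.pdb").exists(), name
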