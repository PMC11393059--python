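"""Readers and writers for the external formats the pipeline touches.

Covers FASTA coding sequences, Newick species trees, orthogroup-count and
genome-metadata tables, PDB ATOM records of predicted structures, Foldseek
tabular pairwise scores, and the YAML configuration consumed by the CLI.

All readers validate rather than silently coerce: malformed records raise
``ValueError`` naming the offending line or field.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

LIFESTYLES = ("thermophilic", "thermotolerant", "mesophilic")

_DNA_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Ordered mapping of sequence id -> uppercase sequence string.

    ``alphabet`` is ``"dna"`` or ``"protein"``; DNA sequences are restricted
    to A, C, G, T, N. ``descriptions`` retains the full FASTA header per id.
    """

    records: dict[str, str]
    alphabet: str = "dna"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for id {name!r}")
            if self.alphabet == "dna":
                bad = set(seq) - _DNA_ALPHABET
                if bad:
                    raise ValueError(
                        f"sequence {name!r} contains non-DNA characters {sorted(bad)}"
                    )

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path, alphabet: str = "dna") -> SequenceSet:
    """Read a FASTA file; ids are the header token before the first whitespace."""
    path = Path(path)
    records: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
        descriptions[rec.id] = rec.description
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    logger.info("read_fasta: %d sequences from %s", len(records), path)
    return SequenceSet(records=records, alphabet=alphabet, descriptions=descriptions)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in seqs.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, thinly wrapping :class:`dendropy.Tree`."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        self.tree.calc_node_root_distances()
        return max(leaf.root_distance for leaf in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        )
        return s.strip() + ("" if s.strip().endswith(";") else ";")


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced parentheses at character {offset}")
    if depth != 0:
        raise ValueError(
            f"unbalanced parentheses: {depth} unclosed '(' at end of input"
        )


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single Newick tree; missing branch lengths become 0 with a warning."""
    path = Path(path)
    text = path.read_text()
    _check_parentheses(text)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"failed to parse Newick in {path}: {exc}") from exc
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing += 1
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length} in {path}")
    if missing:
        logger.warning(
            "read_newick: %d branch lengths missing in %s, set to 0", missing, path
        )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate tip labels in {path}")
    logger.info("read_newick: %d tips from %s", len(labels), path)
    return Phylogeny(tree=tree)


def write_newick(phy: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phy.as_newick() + "\n")


# ---------------------------------------------------------------------------
# orthogroup counts and genome metadata
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupMatrix:
    """Non-negative integer counts, orthogroups (rows) x genomes (columns)."""

    counts: pd.DataFrame
    lifestyles: pd.Series | None = None  # indexed by genome id

    @property
    def orthogroups(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        return self.counts >= 1


def read_count_matrix(path: str | Path, transpose: bool = False) -> OrthogroupMatrix:
    """Read a TSV of orthogroup counts (first column orthogroup id).

    ``transpose=True`` accepts the genomes-as-rows orientation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"empty count matrix in {path}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna().argmax()]
            raise ValueError(
                f"non-integer cell at row {row!r}, column {col!r} in {path}"
            )
        if not np.allclose(numeric % 1, 0):
            row = df.index[(numeric % 1 != 0).argmax()]
            raise ValueError(
                f"non-integer cell at row {row!r}, column {col!r} in {path}"
            )
        if (numeric < 0).any():
            row = df.index[(numeric < 0).argmax()]
            raise ValueError(
                f"negative count at row {row!r}, column {col!r} in {path}"
            )
        out[col] = numeric.astype(int)
    if transpose:
        out = out.T
    if out.index.duplicated().any():
        dup = out.index[out.index.duplicated()][0]
        raise ValueError(f"duplicate orthogroup id {dup!r} in {path}")
    out.index.name = "orthogroup"
    out.columns.name = None
    logger.info(
        "read_count_matrix: %d orthogroups x %d genomes from %s",
        out.shape[0], out.shape[1], path,
    )
    return OrthogroupMatrix(counts=out)


def write_count_matrix(matrix: OrthogroupMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="orthogroup")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the genome metadata table (genome id, lifestyle, optional clade,
    assembly_size_mbp); returns a DataFrame indexed by genome id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "genome" not in df.columns or "lifestyle" not in df.columns:
        raise ValueError(
            f"metadata {path} must have 'genome' and 'lifestyle' columns; "
            f"found {list(df.columns)}"
        )
    bad = set(df["lifestyle"]) - set(LIFESTYLES)
    if bad:
        raise ValueError(
            f"unknown lifestyle value(s) {sorted(bad)} in {path}; "
            f"allowed: {list(LIFESTYLES)}"
        )
    if df["genome"].duplicated().any():
        dup = df["genome"][df["genome"].duplicated()].iloc[0]
        raise ValueError(f"duplicate genome id {dup!r} in {path}")
    df = df.set_index("genome")
    if "assembly_size_mbp" in df.columns:
        df["assembly_size_mbp"] = pd.to_numeric(df["assembly_size_mbp"])
    logger.info("read_metadata: %d genomes from %s", len(df), path)
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="genome", float_format="%.4f")


def attach_metadata(matrix: OrthogroupMatrix, meta: pd.DataFrame) -> OrthogroupMatrix:
    """Join lifestyle labels onto a count matrix, checking genome coverage."""
    missing = set(matrix.genomes) - set(meta.index)
    if missing:
        raise ValueError(
            f"matrix genomes absent from metadata: {sorted(missing)[:5]}"
        )
    return OrthogroupMatrix(
        counts=matrix.counts,
        lifestyles=meta.loc[matrix.genomes, "lifestyle"],
    )


def assembly_size_gap(meta: pd.DataFrame, genome_a: str, genome_b: str) -> float:
    """Absolute assembly-size difference (Mbp) between two genomes."""
    if "assembly_size_mbp" not in meta.columns:
        raise ValueError("metadata has no assembly_size_mbp column")
    return float(abs(meta.loc[genome_a, "assembly_size_mbp"]
                     - meta.loc[genome_b, "assembly_size_mbp"]))


# ---------------------------------------------------------------------------
# protein structures (PDB v3.3 ATOM records)
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Flat atom table for the first model of a PDB file.

    ``atoms`` columns: residue_index, residue_name, atom_name, x, y, z.
    """

    atoms: pd.DataFrame
    name: str = ""

    def residue_names(self) -> pd.Series:
        return self.atoms.drop_duplicates("residue_index").set_index(
            "residue_index"
        )["residue_name"]


def read_pdb(path: str | Path) -> StructureModel:
    """Parse ATOM records of the first model; fixed columns per PDB v3.3.

    HETATM, TER and further models are ignored; only blank or 'A' altlocs
    are kept. A malformed ATOM line raises ``ValueError`` with its line number.
    """
    path = Path(path)
    rows = []
    model_seen = 0
    first_chain: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                model_seen += 1
                if model_seen > 1:
                    break
            elif rec == "ENDMDL":
                break
            if rec != "ATOM  ":
                continue
            try:
                atom_name = line[12:16].strip()
                altloc = line[16]
                res_name = line[17:20].strip()
                chain = line[21]
                res_index = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"malformed ATOM record at line {lineno} of {path}: {exc}"
                ) from exc
            if altloc not in (" ", "A"):
                continue
            if first_chain is None:
                first_chain = chain
            elif chain != first_chain:
                continue
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError(
                    f"non-finite coordinate at line {lineno} of {path}"
                )
            rows.append((res_index, res_name, atom_name, x, y, z))
    if not rows:
        raise ValueError(f"no ATOM records found in {path}")
    atoms = pd.DataFrame(
        rows, columns=["residue_index", "residue_name", "atom_name", "x", "y", "z"]
    )
    res_order = atoms["residue_index"].drop_duplicates()
    if not res_order.is_monotonic_increasing:
        raise ValueError(f"residue indices not strictly increasing in {path}")
    logger.info("read_pdb: %d atoms from %s", len(atoms), path)
    return StructureModel(atoms=atoms, name=path.stem)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a minimal single-chain PDB file from a flat atom table."""
    element_of = {"CA": "C", "SG": "S", "N": "N", "C": "C", "O": "O"}
    with open(path, "w") as fh:
        for serial, row in enumerate(structure.atoms.itertuples(), start=1):
            name = row.atom_name
            # PDB atom-name column convention: 1-3 char names start in col 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<3s} A{resi:>4d}    "
                "{x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
                "          {elem:>2s}\n".format(
                    serial=serial,
                    name=padded,
                    res=row.residue_name,
                    resi=row.residue_index,
                    x=row.x, y=row.y, z=row.z,
                    occ=1.0, b=0.0,
                    elem=element_of.get(name, name[0]),
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# pairwise structural scores (Foldseek tabular output)
# ---------------------------------------------------------------------------

@dataclass
class PairwiseScoreTable:
    """Rows of (query, target, fident, tmscore), self-pairs dropped."""

    scores: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return sorted(set(self.scores["query"]) | set(self.scores["target"]))


def read_foldseek_tsv(
    path: str | Path,
    columns: tuple[str, str, str, str] = ("query", "target", "fident", "alntmscore"),
) -> PairwiseScoreTable:
    """Read Foldseek tabular output; column names configurable.

    Scores outside [0, 1] by more than 1e-6 are an error; values within the
    tolerance are clamped. Self-pairs are dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(
            f"columns {sorted(missing)} not found in {path}; have {list(df.columns)}"
        )
    q, t, fid, tm = columns
    out = df[[q, t, fid, tm]].copy()
    out.columns = ["query", "target", "fident", "tmscore"]
    for col in ("fident", "tmscore"):
        vals = pd.to_numeric(out[col], errors="raise").astype(float)
        if ((vals < -1e-6) | (vals > 1 + 1e-6)).any():
            i = int(((vals < -1e-6) | (vals > 1 + 1e-6)).argmax())
            raise ValueError(
                f"{col} value {vals.iloc[i]} outside [0, 1] at data row {i} of {path}"
            )
        out[col] = vals.clip(0.0, 1.0)
    n_self = int((out["query"] == out["target"]).sum())
    out = out[out["query"] != out["target"]].reset_index(drop=True)
    logger.info(
        "read_foldseek_tsv: %d pairs (%d self-pairs dropped) from %s",
        len(out), n_self, path,
    )
    return PairwiseScoreTable(scores=out)


def write_foldseek_tsv(table: PairwiseScoreTable, path: str | Path) -> None:
    df = table.scores.rename(columns={"tmscore": "alntmscore"})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
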