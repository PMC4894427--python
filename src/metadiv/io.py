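"""Flat-file input/output for the comparative-metabolomics pipeline.

All tables are UTF-8, tab-delimited, with ``#``-prefixed comment lines
ignored. Identifiers are sorted lexicographically after load so that
downstream permutation seeds are reproducible regardless of file row order.

Tables
------
abundance.tsv
    metabolites x measurements matrix of log2 intensities; first column
    holds metabolite ids, header row holds measurement ids.
samples.tsv
    one row per measurement: measurement_id, species, individual,
    replicate, batch, sex.
compound_reaction.tsv / reaction_enzyme.tsv / compound_pathway.tsv
    two-column edge lists of the KEGG-style tripartite reaction network.
expression_lr.tsv
    precomputed per-gene differential-expression statistics, or a raw
    genes x individuals expression matrix (``read_expression_matrix``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CrossReferenceError, FormatError, ParseError

logger = logging.getLogger(__name__)

SPECIES = ("human", "chimpanzee", "rhesus")
SPECIES_PAIRS = ("HC", "HR", "CR")
PAIR_MEMBERS = {"HC": ("human", "chimpanzee"),
                "HR": ("human", "rhesus"),
                "CR": ("chimpanzee", "rhesus")}

SAMPLE_COLUMNS = ["measurement_id", "species", "individual",
                  "replicate", "batch", "sex"]

_FLOAT_FMT = "%.12g"  # >= 10 significant digits for stable round-trips


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Log-scale metabolite intensities, metabolites x measurements.

    ``data`` is a DataFrame indexed by metabolite id with measurement ids
    as columns. Construction validates uniqueness and numeric dtype.
    """

    data: pd.DataFrame

    def __post_init__(self):
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicated metabolite id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicated measurement id {dup!r}")
        if idx.isna().any() or cols.isna().any():
            raise FormatError("missing metabolite or measurement identifier")
        self.data = self.data.astype(float)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def measurement_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def canonical(self) -> "AbundanceMatrix":
        """Return a copy with rows and columns sorted lexicographically."""
        return AbundanceMatrix(
            self.data.sort_index(axis=0).sort_index(axis=1))

    def drop_measurements(self, ids) -> "AbundanceMatrix":
        keep = [c for c in self.data.columns if c not in set(ids)]
        return AbundanceMatrix(self.data[keep])


@dataclass
class SampleTable:
    """Per-measurement metadata: species, individual, replicate, batch, sex."""

    data: pd.DataFrame  # indexed by measurement_id

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            raise FormatError("duplicated measurement id in sample table")
        missing = [c for c in SAMPLE_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        bad = set(df["species"]) - set(SPECIES)
        if bad:
            raise FormatError(f"unknown species labels: {sorted(bad)}")
        pairs = df[["individual", "replicate"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise FormatError("duplicate (individual, replicate) pair")
        sp_per_ind = df.groupby("individual")["species"].nunique()
        if (sp_per_ind > 1).any():
            bad_ind = sp_per_ind[sp_per_ind > 1].index[0]
            raise FormatError(
                f"individual {bad_ind!r} mapped to more than one species")

    @property
    def measurement_ids(self) -> list[str]:
        return list(self.data.index)

    def species_of(self, measurement_ids) -> np.ndarray:
        return self.data.loc[list(measurement_ids), "species"].to_numpy()

    def subset(self, measurement_ids) -> "SampleTable":
        return SampleTable(self.data.loc[list(measurement_ids)])

    def canonical(self) -> "SampleTable":
        return SampleTable(self.data.sort_index())


@dataclass
class ReactionNetwork:
    """Tripartite compound-reaction-enzyme links plus pathway memberships."""

    compound_reaction: frozenset = field(default_factory=frozenset)
    reaction_enzyme: frozenset = field(default_factory=frozenset)
    compound_pathway: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.compound_reaction = frozenset(self.compound_reaction)
        self.reaction_enzyme = frozenset(self.reaction_enzyme)
        self.compound_pathway = frozenset(self.compound_pathway)
        self._reactions_of = {}
        for c, r in self.compound_reaction:
            self._reactions_of.setdefault(c, set()).add(r)
        self._compounds_of = {}
        for c, r in self.compound_reaction:
            self._compounds_of.setdefault(r, set()).add(c)
        self._enzymes_of = {}
        for r, e in self.reaction_enzyme:
            self._enzymes_of.setdefault(r, set()).add(e)
        self._reactions_of_enzyme = {}
        for r, e in self.reaction_enzyme:
            self._reactions_of_enzyme.setdefault(e, set()).add(r)
        self._pathway_members = {}
        for c, p in self.compound_pathway:
            self._pathway_members.setdefault(p, set()).add(c)

    # -- namespaces ---------------------------------------------------------
    @property
    def compounds(self) -> set:
        return ({c for c, _ in self.compound_reaction}
                | {c for c, _ in self.compound_pathway})

    @property
    def reactions(self) -> set:
        return ({r for _, r in self.compound_reaction}
                | {r for r, _ in self.reaction_enzyme})

    @property
    def enzymes(self) -> set:
        return {e for _, e in self.reaction_enzyme}

    @property
    def pathways(self) -> set:
        return {p for _, p in self.compound_pathway}

    # -- lookups ------------------------------------------------------------
    def reactions_of(self, compound) -> set:
        return set(self._reactions_of.get(compound, set()))

    def compounds_of_reaction(self, reaction) -> set:
        return set(self._compounds_of.get(reaction, set()))

    def enzymes_of_reaction(self, reaction) -> set:
        return set(self._enzymes_of.get(reaction, set()))

    def reactions_of_enzyme(self, enzyme) -> set:
        return set(self._reactions_of_enzyme.get(enzyme, set()))

    def compounds_of_enzyme(self, enzyme) -> set:
        out = set()
        for r in self._reactions_of_enzyme.get(enzyme, set()):
            out |= self._compounds_of.get(r, set())
        return out

    def pathway_members(self, pathway) -> set:
        return set(self._pathway_members.get(pathway, set()))

    def degree(self, compound) -> int:
        """Number of distinct reactions a compound participates in."""
        return len(self._reactions_of.get(compound, ()))

    def same_reaction(self, c1, c2) -> bool:
        return bool(self._reactions_of.get(c1, set())
                    & self._reactions_of.get(c2, set()))

    def dangling_reactions(self) -> set:
        """Reactions with enzymes but no compound membership."""
        return ({r for r, _ in self.reaction_enzyme}
                - {r for _, r in self.compound_reaction})

    def load_report(self) -> dict:
        return {
            "n_compounds": len(self.compounds),
            "n_reactions": len(self.reactions),
            "n_enzymes": len(self.enzymes),
            "n_pathways": len(self.pathways),
            "n_dangling_reactions": len(self.dangling_reactions()),
            "dangling_reactions": sorted(self.dangling_reactions()),
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw):
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


def read_abundance(path, metadata_path, canonical=True,
                   impute_missing=False):
    """Read an abundance matrix with its sample metadata.

    Returns a validated ``(AbundanceMatrix, SampleTable)`` pair with the
    matrix columns aligned to the metadata rows. Missing cells are
    rejected unless ``impute_missing`` replaces them with the per-metabolite
    minimum (the baseline-replacement idiom of GC-MS processing pipelines).
    """
    raw = _read_tsv(path)
    raw = raw.set_index(raw.columns[0])
    num = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            i = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"non-numeric cell {raw[col].iloc[i]!r} for metabolite "
                f"{raw.index[i]!r}", line=i + 2, column=j + 2)
        num[col] = converted
    if num.isna().any().any():
        if impute_missing:
            num = num.apply(lambda row: row.fillna(row.min()), axis=1)
        else:
            raise ParseError("missing cells in abundance matrix "
                             "(pass impute_missing=True to impute)")
    matrix = AbundanceMatrix(num)

    meta = _read_tsv(metadata_path)
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    meta["replicate"] = meta["replicate"].astype(int)
    samples = SampleTable(meta.set_index("measurement_id"))

    extra = set(matrix.measurement_ids) - set(samples.measurement_ids)
    if extra:
        raise CrossReferenceError(
            f"measurements absent from sample table: {sorted(extra)}")
    samples = samples.subset(matrix.measurement_ids)
    if canonical:
        matrix = matrix.canonical()
        samples = samples.subset(matrix.measurement_ids)
    return matrix, samples


def write_abundance(matrix: AbundanceMatrix, path):
    matrix.data.to_csv(path, sep="\t", index_label="metabolite_id",
                       float_format=_FLOAT_FMT)


def write_samples(samples: SampleTable, path):
    samples.data.to_csv(path, sep="\t", index_label="measurement_id")


def read_samples(path) -> SampleTable:
    meta = _read_tsv(path)
    meta["replicate"] = meta["replicate"].astype(int)
    return SampleTable(meta.set_index("measurement_id")).canonical()


def _read_edges(path, n_cols=2):
    """Read a two-column tab-delimited edge list; '#' lines ignored."""
    edges = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols or any(not p.strip() for p in parts):
                raise ParseError(f"malformed edge line {line!r}",
                                 line=lineno)
            edges.add(tuple(p.strip() for p in parts))
    if not edges:
        logger.warning("empty edge list in %s", path)
        warnings.warn(f"empty edge list in {path}", stacklevel=2)
    return edges


def read_network(compound_reaction_path, reaction_enzyme_path,
                 compound_pathway_path) -> ReactionNetwork:
    """Load the tripartite network from three two-column edge lists.

    Duplicate lines collapse to single edges; reactions referenced by
    enzymes but absent from the compound side are kept but flagged in
    ``ReactionNetwork.load_report()``.
    """
    net = ReactionNetwork(
        compound_reaction=_read_edges(compound_reaction_path),
        reaction_enzyme=_read_edges(reaction_enzyme_path),
        compound_pathway=_read_edges(compound_pathway_path),
    )
    report = net.load_report()
    logger.info("network loaded: %s", report)
    if report["n_dangling_reactions"]:
        logger.warning("dangling reactions (enzyme-only): %s",
                       report["dangling_reactions"])
    return net


def write_network(network: ReactionNetwork, out_dir):
    import os
    os.makedirs(out_dir, exist_ok=True)
    for name, edges in [("compound_reaction", network.compound_reaction),
                        ("reaction_enzyme", network.reaction_enzyme),
                        ("compound_pathway", network.compound_pathway)]:
        df = pd.DataFrame(sorted(edges))
        df.to_csv(f"{out_dir}/{name}.tsv", sep="\t", header=False,
                  index=False)


def read_pathways_gmt(path) -> set:
    """Read pathway memberships from GMT (id, description, members...)."""
    edges = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs id, description, members",
                                 line=lineno)
            pw = parts[0]
            for c in parts[2:]:
                if c:
                    edges.add((c, pw))
    return edges


def read_expression_lr(path) -> pd.DataFrame:
    """Read precomputed per-gene differential-expression statistics.

    Columns: gene_id, species_pair, LR, p, q, median_diff.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "species_pair", "LR", "p", "q", "median_diff"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"expression table missing columns: {sorted(missing)}")
    bad = set(df["species_pair"]) - set(SPECIES_PAIRS)
    if bad:
        raise FormatError(f"unknown species pairs: {sorted(bad)}")
    return df


def read_expression_matrix(path, metadata_path):
    """Read a raw genes x individuals expression matrix.

    The metadata maps each individual (one column per individual) to a
    species; returns ``(DataFrame genes x individuals, Series species)``.
    """
    raw = _read_tsv(path)
    raw = raw.set_index(raw.columns[0]).astype(float)
    meta = _read_tsv(metadata_path).set_index("individual")
    missing = set(raw.columns) - set(meta.index)
    if missing:
        raise CrossReferenceError(
            f"individuals absent from metadata: {sorted(missing)}")
    return raw.sort_index(), meta.loc[raw.columns, "species"]


def write_results_table(records: pd.DataFrame, path):
    """Write a results table with >=10 significant digits per float."""
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
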