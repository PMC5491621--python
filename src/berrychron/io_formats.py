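"""Tabular and network I/O with a fixed, documented dialect.

Dialect
-------
UTF-8, tab-separated, ``.`` decimal point, no thousands separators.
Zeros mean "not detected"; the token ``NA`` is rejected on input so that
missingness cannot silently change meaning. Stage order is taken from the
design file's row order, never lexicographic (a label such as ``EL37.5``
sorts wrongly as text).

Abundance tables are features x samples: first column ``feature_id``,
optional second column ``kind`` (one of ``metabolite_gc``,
``metabolite_lc``, ``protein``), remaining columns one per sample id.
Spectral-count tables carry a ``length`` column (protein sequence length
in residues) instead of ``kind``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

FEATURE_KINDS = ("metabolite_gc", "metabolite_lc", "protein")

DESIGN_COLUMNS = (
    "sample_id",
    "stage",
    "replicate",
    "fresh_weight",
    "internal_standard_intensity",
    "total_ion_intensity",
)


@dataclass
class SampleDesign:
    """Sample sheet: ordered stages, replicate ids, per-sample normalizers.

    ``table`` is indexed by sample id with columns ``stage``, ``replicate``,
    ``fresh_weight`` (mg), ``internal_standard_intensity`` and
    ``total_ion_intensity`` (arbitrary units). ``stage_order`` is the total
    order of stage labels, taken from first appearance in the input.
    """

    table: pd.DataFrame
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stage_order:
            self.stage_order = list(dict.fromkeys(self.table["stage"]))
        pairs = list(zip(self.table["stage"], self.table["replicate"]))
        if len(set(pairs)) != len(pairs):
            dup = next(p for p in pairs if pairs.count(p) > 1)
            raise ValueError(f"duplicate (stage, replicate) pair: {dup}")
        unknown = set(self.table["stage"]) - set(self.stage_order)
        if unknown:
            raise ValueError(f"stages missing from stage_order: {sorted(unknown)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_stages(self) -> int:
        return len(self.stage_order)

    def samples_of_stage(self, stage: str) -> list[str]:
        return list(self.table.index[self.table["stage"] == stage])

    def stage_of(self) -> pd.Series:
        """Sample id -> stage label."""
        return self.table["stage"]


@dataclass
class AbundanceMatrix:
    """Non-negative feature x sample abundance values.

    ``values``: DataFrame indexed by feature id, columns = sample ids.
    ``kinds``: per-feature kind, one of :data:`FEATURE_KINDS`.
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        bad = set(self.kinds) - set(FEATURE_KINDS)
        if bad:
            raise ValueError(f"unknown feature kind(s): {sorted(bad)}")
        self.kinds = self.kinds.reindex(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def subset(self, feature_ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[feature_ids], self.kinds.loc[feature_ids])

    def of_kind(self, *kinds: str) -> "AbundanceMatrix":
        mask = self.kinds.isin(kinds)
        return AbundanceMatrix(self.values.loc[mask], self.kinds.loc[mask])


def _parse_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    """Convert string cells to float, rejecting NA tokens and locating errors."""
    out = {}
    for col in df.columns:
        raw = df[col]
        if raw.astype(str).str.strip().str.upper().isin(["NA", "NAN", ""]).any():
            row = raw.index[raw.astype(str).str.strip().str.upper().isin(["NA", "NAN", ""])][0]
            raise ValueError(
                f"{path}: missing/NA token at row {row!r}, column {col!r}; "
                "zeros are the only absence marker in this dialect"
            )
        converted = pd.to_numeric(raw, errors="coerce")
        if converted.isna().any():
            row = raw.index[converted.isna()][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}: {raw[row]!r}")
        out[col] = converted.astype(float)
    return pd.DataFrame(out, index=df.index)


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design file missing column(s) {sorted(missing)}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id: {dup!r}")
    numeric = _parse_numeric(
        df[["fresh_weight", "internal_standard_intensity", "total_ion_intensity"]], path
    )
    table = pd.DataFrame(
        {
            "stage": df["stage"],
            "replicate": df["replicate"],
            "fresh_weight": numeric["fresh_weight"],
            "internal_standard_intensity": numeric["internal_standard_intensity"],
            "total_ion_intensity": numeric["total_ion_intensity"],
        }
    )
    return SampleDesign(table)


def write_design(design: SampleDesign, path) -> None:
    df = design.table.reset_index(names="sample_id")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_abundance(path, design_path) -> tuple[AbundanceMatrix, SampleDesign]:
    """Read an abundance TSV aligned against its sample design.

    The header row carries sample ids; the first column carries feature
    ids. Unknown sample ids, duplicate feature ids, NA tokens and
    non-numeric cells are hard errors naming the offender.
    """
    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    feat_col = df.columns[0]
    df = df.set_index(feat_col)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id: {dup!r}")
    if "kind" in df.columns:
        kinds = df.pop("kind")
    else:
        kinds = pd.Series("metabolite_gc", index=df.index)
    unknown = set(df.columns) - set(design.samples)
    if unknown:
        raise ValueError(f"{path}: unknown sample id {sorted(unknown)[0]!r} not in design")
    missing = set(design.samples) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample {sorted(missing)[0]!r} from design absent in matrix")
    values = _parse_numeric(df, path)[design.samples]
    values.index.name = None
    values.columns.name = None
    return AbundanceMatrix(values, kinds), design


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    df = matrix.values.copy()
    df.insert(0, "kind", matrix.kinds)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_spectral_counts(path, design_path):
    """Read a spectral-count TSV (``length`` column + sample columns)."""
    from .quantify import SpectralCountTable  # local import avoids a cycle

    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate protein id: {dup!r}")
    if "length" not in df.columns:
        raise ValueError(f"{path}: spectral-count table requires a 'length' column")
    lengths = _parse_numeric(df[["length"]], path)["length"].astype(int)
    counts = _parse_numeric(df.drop(columns="length"), path)[design.samples]
    return SpectralCountTable(counts.round().astype(int), lengths), design


def write_spectral_counts(table, path) -> None:
    df = table.counts.copy()
    df.insert(0, "length", table.lengths)
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t")


# --- network exports ------------------------------------------------------


def write_edge_table(edges, path) -> None:
    rows = [
        {"cause": e.cause, "effect": e.effect, "lag": e.lag, "F": e.F, "p": e.p, "T": e.T}
        for e in edges
    ]
    pd.DataFrame(rows, columns=["cause", "effect", "lag", "F", "p", "T"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_network_sif(network, path) -> None:
    """SIF export for Cytoscape: one ``cause granger_lagK effect`` line per edge."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in network.edges:
            fh.write(f"{e.cause}\tgranger_lag{e.lag}\t{e.effect}\n")


def _as_multigraph(network) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for node in network.nodes:
        g.add_node(
            node,
            neighbors=int(network.neighbor_count.get(node, 0)),
            in_degree=int(network.in_degree.get(node, 0)),
            out_degree=int(network.out_degree.get(node, 0)),
        )
    for e in network.edges:
        g.add_edge(e.cause, e.effect, lag=int(e.lag), F=float(e.F), p=float(e.p))
    return g


def write_network_graphml(network, path) -> None:
    """GraphML export: F, p, lag as edge attributes; neighbor degree on nodes."""
    nx.write_graphml(_as_multigraph(network), path)


def read_network_graphml(path) -> nx.MultiDiGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    return g


def write_ground_truth(truth, directory) -> None:
    """Ground-truth sidecars for a synthetic dataset: edge list + membership."""
    directory = Path(directory)
    pd.DataFrame(
        [
            {"cause": c, "effect": e, "lag": lag, "coefficient": coef, "level": level}
            for (c, e, lag, coef, level) in truth.edge_records()
        ],
        columns=["cause", "effect", "lag", "coefficient", "level"],
    ).to_csv(directory / "true_edges.tsv", sep="\t", index=False)
    pd.Series(truth.archetype_of_feature, name="archetype").rename_axis("feature_id").to_csv(
        directory / "true_membership.tsv", sep="\t"
    )
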