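"""Mixed-type table and variable-spec I/O, plus network serialization.

A dataset is a subjects x variables table in which every column is
declared ``binary``, ``ordinal``, or ``continuous``.  Ordinal and binary
columns carry an explicit ordered list of levels; internally levels are
stored as rank codes 0..K-1 because the model only uses their order.
Missing cells are flagged in a boolean mask and are never imputed at
load time — the EM algorithm handles them downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

MISSING_TOKENS = {"", "na", "nan"}

VALID_VTYPES = ("binary", "ordinal", "continuous")
VALID_GROUPS = ("physical_functioning", "nutrient", "covariate",
                "study_dummy", "other")


@dataclass
class VariableSpec:
    """Declaration of one column: its name, measurement type and grouping.

    ``levels`` lists the ordered admissible values for binary/ordinal
    variables (external labels; order defines the latent ordering).
    ``marginal`` optionally carries generative marginal targets used only
    by the synthetic-data module (e.g. lognormal mean/sd, level
    probabilities); it plays no role in estimation.
    """

    name: str
    vtype: str
    levels: list | None = None
    group: str = "other"
    marginal: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.vtype not in VALID_VTYPES:
            raise ValueError(f"{self.name}: unknown variable type {self.vtype!r}")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")
        if self.vtype == "continuous":
            if self.levels is not None:
                raise ValueError(f"{self.name}: continuous variables take no levels")
        else:
            if self.levels is None:
                raise ValueError(f"{self.name}: {self.vtype} variable needs levels")
            self.levels = list(self.levels)
            if self.vtype == "binary" and len(self.levels) != 2:
                raise ValueError(f"{self.name}: binary requires exactly 2 levels")
            if self.vtype == "ordinal" and len(self.levels) < 2:
                raise ValueError(f"{self.name}: ordinal requires >= 2 levels")
            if len(set(map(str, self.levels))) != len(self.levels):
                raise ValueError(f"{self.name}: duplicate levels")

    @property
    def is_discrete(self) -> bool:
        return self.vtype in ("binary", "ordinal")

    @property
    def n_levels(self) -> int:
        return 0 if self.levels is None else len(self.levels)


@dataclass
class MixedDataset:
    """Validated n x p table with per-column type metadata.

    ``values`` is a float array: continuous cells hold the observation,
    discrete cells hold the level's rank code 0..K-1, and missing cells
    hold NaN.  ``missing_mask`` is True exactly at missing cells.
    """

    values: np.ndarray
    specs: list[VariableSpec]
    missing_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError("dataset needs n >= 2 rows and p >= 2 columns")
        if len(self.specs) != p:
            raise ValueError("one VariableSpec required per column")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if not np.all(np.isnan(self.values[self.missing_mask])):
            raise ValueError("masked cells must be NaN")
        for j, spec in enumerate(self.specs):
            col = self.values[~self.missing_mask[:, j], j]
            if spec.is_discrete:
                codes = np.unique(col)
                if codes.size and (codes.min() < 0 or codes.max() > spec.n_levels - 1
                                   or not np.allclose(codes, np.round(codes))):
                    raise ValueError(f"{spec.name}: cell outside declared levels")
                if codes.size < 2:
                    raise ValueError(
                        f"{spec.name}: discrete column must attain >= 2 observed levels")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def subset_rows(self, idx: np.ndarray) -> "MixedDataset":
        """Row-resampled copy (used by the bootstrap)."""
        return MixedDataset(self.values[idx], self.specs, self.missing_mask[idx])


# ---------------------------------------------------------------------------
# spec files


def read_variable_specs(path) -> list[VariableSpec]:
    """Read a YAML variable-spec file (one entry per column)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("variables", doc)
    specs = []
    for name, entry in entries.items():
        if isinstance(entry, str):
            entry = {"type": entry}
        specs.append(VariableSpec(
            name=str(name),
            vtype=entry.get("type", entry.get("vtype")),
            levels=entry.get("levels"),
            group=entry.get("group", "other"),
            marginal=entry.get("marginal"),
        ))
    return specs


def write_variable_specs(specs: list[VariableSpec], path) -> None:
    doc = {"variables": {}}
    for s in specs:
        entry = {"type": s.vtype, "group": s.group}
        if s.levels is not None:
            entry["levels"] = [_plain(v) for v in s.levels]
        if s.marginal is not None:
            entry["marginal"] = {k: _plain(v) for k, v in s.marginal.items()}
        doc["variables"][s.name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return [_plain(x) for x in v]
    return v


# ---------------------------------------------------------------------------
# data tables


def _is_missing_token(s: str) -> bool:
    return s.strip().lower() in MISSING_TOKENS


def read_mixed_table(path, spec_path=None, *, specs=None, delimiter=None,
                     max_ordinal_levels: int = 12) -> MixedDataset:
    """Read a CSV/TSV with a header row into a validated :class:`MixedDataset`.

    Column types come from ``spec_path`` (or a ``specs`` list).  With
    neither given, types are inferred heuristically via
    :func:`infer_variable_specs` (a warning is emitted).  Cells equal to
    the empty string, "NA" or "NaN" (case-insensitive) are flagged
    missing, never imputed.
    """
    if specs is None and spec_path is not None:
        specs = read_variable_specs(spec_path)
    df = _read_raw(path, delimiter)
    if specs is None:
        specs = _infer_from_frame(df, max_ordinal_levels)
        warnings.warn("no variable spec given; types inferred heuristically",
                      stacklevel=2)
    return _frame_to_dataset(df, specs)


def _read_raw(path, delimiter) -> pd.DataFrame:
    sep = delimiter
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _frame_to_dataset(df: pd.DataFrame, specs: list[VariableSpec]) -> MixedDataset:
    by_name = {s.name: s for s in specs}
    for col in df.columns:
        if col not in by_name:
            raise ValueError(f"column {col!r} in data is not declared in the spec")
    for name in by_name:
        if name not in df.columns:
            raise ValueError(f"spec declares unknown column {name!r}")
    ordered = [by_name[c] for c in df.columns]
    n, p = df.shape
    values = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    for j, (col, spec) in enumerate(zip(df.columns, ordered)):
        raw = df[col].astype(str)
        miss = raw.map(_is_missing_token).to_numpy()
        mask[:, j] = miss
        obs = raw[~miss].str.strip()
        if spec.vtype == "continuous":
            try:
                values[~miss, j] = obs.astype(float).to_numpy()
            except ValueError as exc:
                raise ValueError(
                    f"{spec.name}: non-numeric cell in continuous column; "
                    "non-ordinal categorical variables are not supported — "
                    "dummy-encode them as binary columns") from exc
        else:
            lut = {str(lv).strip(): k for k, lv in enumerate(spec.levels)}
            codes = obs.map(lut)
            if codes.isna().any():
                bad = obs[codes.isna()].iloc[0]
                raise ValueError(
                    f"{spec.name}: value {bad!r} outside declared levels "
                    f"{spec.levels}")
            values[~miss, j] = codes.to_numpy(dtype=float)
    return MixedDataset(values, ordered, mask)


def infer_variable_specs(path, max_ordinal_levels: int = 12,
                         delimiter=None) -> list[VariableSpec]:
    """Heuristic type inference: integer columns with few distinct values are
    ordinal (2 distinct -> binary), everything else continuous."""
    df = _read_raw(path, delimiter)
    warnings.warn("variable-type inference is heuristic; prefer an explicit "
                  "spec file", stacklevel=2)
    return _infer_from_frame(df, max_ordinal_levels)


def _infer_from_frame(df: pd.DataFrame, max_ordinal_levels: int) -> list[VariableSpec]:
    specs = []
    for col in df.columns:
        raw = df[col].astype(str)
        obs = raw[~raw.map(_is_missing_token)].str.strip()
        vals = pd.to_numeric(obs, errors="coerce")
        if vals.isna().any():
            raise ValueError(
                f"{col}: non-numeric values; declare this column explicitly "
                "(non-ordinal categoricals must be dummy-encoded)")
        uniq = np.unique(vals.to_numpy())
        integral = np.allclose(uniq, np.round(uniq))
        if integral and uniq.size == 2:
            specs.append(VariableSpec(col, "binary", levels=[int(u) for u in uniq]))
        elif integral and uniq.size <= max_ordinal_levels:
            specs.append(VariableSpec(col, "ordinal", levels=[int(u) for u in uniq]))
        else:
            specs.append(VariableSpec(col, "continuous"))
    return specs


def write_mixed_table(data: MixedDataset, path, *, delimiter=",") -> None:
    """Write the dataset back to CSV/TSV with external level labels and empty
    strings at missing cells (round-trips through :func:`read_mixed_table`)."""
    cols = {}
    for j, spec in enumerate(data.specs):
        col = np.empty(data.n, dtype=object)
        miss = data.missing_mask[:, j]
        col[miss] = ""
        if spec.is_discrete:
            codes = data.values[~miss, j].astype(int)
            labels = np.asarray([str(lv) for lv in spec.levels], dtype=object)
            col[~miss] = labels[codes]
        else:
            col[~miss] = [repr(float(v)) for v in data.values[~miss, j]]
        cols[spec.name] = col
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# network outputs


def _edge_table(omega: np.ndarray, names, partials: np.ndarray,
                freq: np.ndarray | None) -> pd.DataFrame:
    p = omega.shape[0]
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if omega[i, j] != 0.0:
                rows.append({
                    "node_i": names[i],
                    "node_j": names[j],
                    "partial_correlation": partials[i, j],
                    "bootstrap_frequency": (
                        "" if freq is None else freq[i, j]),
                })
    return pd.DataFrame(rows, columns=["node_i", "node_j",
                                       "partial_correlation",
                                       "bootstrap_frequency"])


def write_network(network, path, fmt: str = "edge_tsv", *, stability=None,
                  report=None, certainty_thresholds=(0.5, 0.75, 0.9)) -> None:
    """Serialize a selected network.

    Parameters
    ----------
    network : SelectedNetwork
        Finalized estimate (precision matrix, partial correlations, groups).
    fmt : {"edge_tsv", "adjacency_csv", "graphml", "json_report"}
    stability : StabilityReport, optional
        Merges bootstrap edge frequencies into the output.
    report : PenaltyPath, optional
        Required for ``json_report``: supplies the penalty grid, eBIC curve
        and EM iteration counts.
    """
    omega = network.omega
    names = network.names
    partials = network.partials
    freq = None if stability is None else stability.frequency
    if fmt == "edge_tsv":
        _edge_table(omega, names, partials, freq).to_csv(path, sep="\t",
                                                         index=False)
    elif fmt == "adjacency_csv":
        pd.DataFrame(partials, index=names, columns=names).to_csv(path)
    elif fmt == "graphml":
        g = nx.Graph()
        groups = network.node_groups or {}
        for name in names:
            g.add_node(name, group=groups.get(name, "other"))
        p = omega.shape[0]
        for i in range(p):
            for j in range(i + 1, p):
                if omega[i, j] != 0.0:
                    attrs = {"partial_correlation": float(partials[i, j])}
                    if freq is not None:
                        f = float(freq[i, j])
                        attrs["bootstrap_frequency"] = f
                        attrs["certainty_class"] = int(
                            sum(f >= t for t in certainty_thresholds))
                    g.add_edge(names[i], names[j], **attrs)
        nx.write_graphml(g, path)
    elif fmt == "json_report":
        if report is None:
            raise ValueError("json_report requires the fitted PenaltyPath")
        doc = {
            "lambda_grid": [float(l) for l in report.grid],
            "ebic": [float(e) for e in report.ebic],
            "selected_lambda": float(network.lam_hat),
            "sparsity": float(network.sparsity),
            "em_iterations": [int(e.n_iter) for e in report.estimates],
            "converged": [bool(e.converged) for e in report.estimates],
            "n_edges": [int(np.count_nonzero(np.triu(e.omega, 1)))
                        for e in report.estimates],
            "edges": _edge_table(omega, names, partials, freq).to_dict(
                orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_json_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
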