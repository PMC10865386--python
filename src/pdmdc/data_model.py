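"""Tensor data containers, long-format I/O and preprocessing.

Postprandial metabolomics from a crossover intervention is a four-way
array ``X`` indexed (metabolite, time, individual, diet).  This module
holds that container (:class:`ResponseTensor`), the per-diet input
vectors (:class:`DietInputMatrix`), the clinical baseline table, and the
preprocessing steps applied before system identification:

* baseline subtraction — the pre-meal sample (t=0) is subtracted from
  each trajectory so only the postprandial excursion remains;
* per-diet standardization to unit variance, for comparable R² across
  diets;
* low-variance metabolite filtering (flat trajectories carry no
  dynamics);
* logarithmic time down-sampling (dense early sampling, sparse late).

Every transform is pure (inputs untouched), appends a tagged entry to
``preprocessing_log``, and can be replayed bit-for-bit on raw data via
:func:`replay_log`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseTensor",
    "DietInputMatrix",
    "ClinicalTable",
    "read_tensor_long",
    "write_tensor_long",
    "read_diet_inputs",
    "read_clinical_table",
    "subtract_baseline",
    "standardize_per_diet",
    "invert_standardization",
    "filter_low_variance",
    "downsample_logarithmic",
    "replay_log",
]

_LONG_COLUMNS = ["metabolite", "time_index", "individual", "diet", "value"]


@dataclass(frozen=True)
class ResponseTensor:
    """Four-way response tensor X (metabolite × time × individual × diet).

    ``time_points`` are ordinal indices; t=0 is the pre-meal baseline
    sample.  ``preprocessing_log`` is an ordered list of
    ``{"op": name, "params": {...}}`` entries recording every transform
    applied since load.
    """

    values: np.ndarray
    metabolite_ids: tuple[str, ...]
    time_points: tuple[int, ...]
    individual_ids: tuple[str, ...]
    diet_ids: tuple[str, ...]
    preprocessing_log: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "time_points", tuple(int(t) for t in self.time_points))
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        object.__setattr__(self, "diet_ids", tuple(self.diet_ids))
        object.__setattr__(self, "preprocessing_log", tuple(self.preprocessing_log))
        if values.ndim != 4:
            raise ValueError(f"expected a 4-way array, got ndim={values.ndim}")
        expected = (
            len(self.metabolite_ids),
            len(self.time_points),
            len(self.individual_ids),
            len(self.diet_ids),
        )
        if values.shape != expected:
            raise ValueError(f"axis labels {expected} do not match array shape {values.shape}")
        if min(values.shape) < 1:
            raise ValueError("all tensor dimensions must be >= 1")
        if not np.all(np.isfinite(values)):
            raise ValueError("tensor contains missing or non-finite values")
        norm_tags = [e["op"] for e in self.preprocessing_log]
        if len(norm_tags) != len(set(norm_tags)):
            dupes = {t for t in norm_tags if norm_tags.count(t) > 1}
            # the same filter may legitimately never repeat either; the
            # log is an audit trail of a linear pipeline
            raise ValueError(f"preprocessing tag applied twice: {sorted(dupes)}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[2]

    @property
    def n_diets(self) -> int:
        return self.values.shape[3]

    def has_tag(self, op: str) -> bool:
        return any(e["op"] == op for e in self.preprocessing_log)

    def series(self, individual: int | str, diet: int | str) -> np.ndarray:
        """Return the M × T trajectory matrix for one (individual, diet)."""
        i = individual if isinstance(individual, int) else self.individual_ids.index(individual)
        d = diet if isinstance(diet, int) else self.diet_ids.index(diet)
        return self.values[:, :, i, d]

    def _with(self, values: np.ndarray, log_entry: dict | None = None, **updates) -> "ResponseTensor":
        log = self.preprocessing_log + ((log_entry,) if log_entry else ())
        return replace(self, values=values, preprocessing_log=log, **updates)


@dataclass(frozen=True)
class DietInputMatrix:
    """Per-diet impulse input vectors z_{1,d}, one column per diet.

    Rows are input features (e.g. fat/protein/carbohydrate in grams, or
    glucose/triglyceride content in mmol).
    """

    inputs: np.ndarray  # l × D
    input_names: tuple[str, ...]
    diet_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "diet_ids", tuple(self.diet_ids))
        if inputs.ndim != 2:
            raise ValueError("inputs must be a 2-D (feature × diet) matrix")
        if inputs.shape != (len(self.input_names), len(self.diet_ids)):
            raise ValueError("input_names / diet_ids lengths do not match the input matrix")
        if not np.all(np.isfinite(inputs)):
            raise ValueError("diet inputs must be finite")

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_diets(self) -> int:
        return self.inputs.shape[1]

    def vector(self, diet: int | str) -> np.ndarray:
        d = diet if isinstance(diet, int) else self.diet_ids.index(diet)
        return self.inputs[:, d]

    def check_matches(self, tensor: ResponseTensor) -> None:
        if self.diet_ids != tensor.diet_ids:
            raise ValueError(
                f"diet ids {self.diet_ids} do not match tensor diets {tensor.diet_ids}"
            )


@dataclass(frozen=True)
class ClinicalTable:
    """Baseline clinical / anthropometric measures, one row per individual.

    Missing values are permitted (NaN) and flagged via ``has_missing``.
    """

    measures: np.ndarray  # I × C
    measure_names: tuple[str, ...]
    individual_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        measures = np.asarray(self.measures, dtype=float)
        object.__setattr__(self, "measures", measures)
        object.__setattr__(self, "measure_names", tuple(self.measure_names))
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        if measures.shape != (len(self.individual_ids), len(self.measure_names)):
            raise ValueError("clinical table shape does not match its labels")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.measures).any())

    def column(self, measure: str) -> np.ndarray:
        return self.measures[:, self.measure_names.index(measure)]


# ---------------------------------------------------------------------------
# I/O — long-format delimited text
# ---------------------------------------------------------------------------


def read_tensor_long(path: str | Path, *, sep: str = ",", decimal: str = ".",
                     axis_order: dict[str, Sequence] | None = None) -> ResponseTensor:
    """Read a ResponseTensor from long-format delimited text.

    The file must have columns ``metabolite,time_index,individual,diet,value``
    and contain the complete crossing of the four keys exactly once.
    Axis labels are sorted unless an explicit order is given in
    ``axis_order`` (keys: metabolite, time_index, individual, diet).
    """
    df = pd.read_csv(path, sep=sep, decimal=decimal, float_precision="round_trip",
                     dtype={"metabolite": str, "individual": str, "diet": str})
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long-format file lacks columns: {missing_cols}")
    df["time_index"] = df["time_index"].astype(int)

    axis_order = axis_order or {}

    def _labels(col: str) -> list:
        if col in axis_order:
            lab = list(axis_order[col])
            extra = set(df[col]) - set(lab)
            if extra:
                raise ValueError(f"configured order for {col} misses labels {sorted(extra)}")
            return lab
        return sorted(df[col].unique())

    mets = _labels("metabolite")
    times = _labels("time_index")
    inds = _labels("individual")
    diets = _labels("diet")

    keys = list(zip(df["metabolite"], df["time_index"], df["individual"], df["diet"]))
    if len(keys) != len(set(keys)):
        seen: set = set()
        for k in keys:
            if k in seen:
                raise ValueError(f"duplicate key in long-format file: {k}")
            seen.add(k)
    index = {k: v for k, v in zip(keys, df["value"].to_numpy(dtype=float))}

    values = np.empty((len(mets), len(times), len(inds), len(diets)))
    for mi, m in enumerate(mets):
        for ti, t in enumerate(times):
            for ii, i in enumerate(inds):
                for di, d in enumerate(diets):
                    key = (m, t, i, d)
                    if key not in index:
                        raise ValueError(
                            "incomplete tensor: missing entry for "
                            f"(metabolite={m}, time_index={t}, individual={i}, diet={d})"
                        )
                    values[mi, ti, ii, di] = index[key]
    return ResponseTensor(values, mets, times, inds, diets)


def write_tensor_long(tensor: ResponseTensor, path: str | Path, *, sep: str = ",",
                      decimal: str = ".", sidecar: bool = True) -> None:
    """Write a ResponseTensor in canonical long format.

    Rows are emitted in axis order (metabolite outermost, diet
    innermost), so ``write(read(f)) == f`` byte-wise for files produced
    by this writer.  A sidecar JSON ``<path>.meta.json`` stores axis
    labels and the preprocessing log.
    """
    path = Path(path)
    records = []
    for mi, m in enumerate(tensor.metabolite_ids):
        for ti, t in enumerate(tensor.time_points):
            for ii, i in enumerate(tensor.individual_ids):
                for di, d in enumerate(tensor.diet_ids):
                    records.append((m, t, i, d, tensor.values[mi, ti, ii, di]))
    df = pd.DataFrame.from_records(records, columns=_LONG_COLUMNS)
    df.to_csv(path, sep=sep, decimal=decimal, index=False)
    if sidecar:
        meta = {
            "metabolite_ids": list(tensor.metabolite_ids),
            "time_points": list(tensor.time_points),
            "individual_ids": list(tensor.individual_ids),
            "diet_ids": list(tensor.diet_ids),
            "preprocessing_log": [dict(e) for e in tensor.preprocessing_log],
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_diet_inputs(path: str | Path, *, sep: str = ",") -> DietInputMatrix:
    """Read a diet-input table: first column = input feature name, one
    further column per diet."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return DietInputMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)),
                           list(df.columns.astype(str)))


def write_diet_inputs(diets: DietInputMatrix, path: str | Path, *, sep: str = ",") -> None:
    df = pd.DataFrame(diets.inputs, index=list(diets.input_names),
                      columns=list(diets.diet_ids))
    df.to_csv(path, sep=sep, index_label="input")


def read_clinical_table(path: str | Path, *, sep: str = ",") -> ClinicalTable:
    """Read a clinical table: first column = individual id, one column
    per measure; empty cells become NaN."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ClinicalTable(df.to_numpy(dtype=float), list(df.columns.astype(str)),
                         list(df.index.astype(str)))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def subtract_baseline(tensor: ResponseTensor) -> ResponseTensor:
    """Subtract the pre-meal sample x[:, 0, i, d] from every trajectory.

    After this transform the t=0 slice is exactly zero and every
    trajectory measures the postprandial excursion from baseline.
    """
    if tensor.n_times < 2:
        raise ValueError("baseline subtraction needs at least two time points")
    if tensor.has_tag("subtract_baseline"):
        raise ValueError("baseline already subtracted")
    baseline = tensor.values[:, :1, :, :]
    out = tensor.values - baseline
    return tensor._with(out, {"op": "subtract_baseline", "params": {}})


def standardize_per_diet(
    tensor: ResponseTensor, *, mode: str = "per_metabolite", ddof: int = 1,
) -> tuple[ResponseTensor, np.ndarray]:
    """Scale each diet's response to unit variance.

    ``mode='per_metabolite'`` (default) divides every (metabolite, diet)
    slice by its standard deviation over the pooled time × individual
    entries; ``mode='pooled'`` uses one scale per diet over all
    metabolites jointly.  Returns the scaled tensor and the M × D scale
    matrix (broadcast row-wise for pooled mode) so the transform can be
    inverted exactly.
    """
    if tensor.has_tag("standardize_per_diet"):
        raise ValueError("per-diet standardization already applied")
    if mode not in ("per_metabolite", "pooled"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    M, _, _, D = tensor.shape
    scales = np.empty((M, D))
    if mode == "per_metabolite":
        for d in range(D):
            for m in range(M):
                scales[m, d] = np.std(tensor.values[m, :, :, d], ddof=ddof)
    else:
        for d in range(D):
            scales[:, d] = np.std(tensor.values[:, :, :, d], ddof=ddof)
    bad = np.argwhere(scales <= 0.0)
    if bad.size:
        pairs = [(tensor.metabolite_ids[m], tensor.diet_ids[d]) for m, d in bad[:20]]
        raise ValueError(f"zero-variance (metabolite, diet) slices cannot be standardized: {pairs}")
    out = tensor.values / scales[:, None, None, :]
    scaled = tensor._with(out, {"op": "standardize_per_diet",
                                "params": {"mode": mode, "ddof": ddof}})
    return scaled, scales


def invert_standardization(tensor: ResponseTensor, scales: np.ndarray) -> ResponseTensor:
    """Undo :func:`standardize_per_diet` using its returned scales."""
    out = tensor.values * np.asarray(scales)[:, None, None, :]
    log = tuple(e for e in tensor.preprocessing_log if e["op"] != "standardize_per_diet")
    return replace(tensor, values=out, preprocessing_log=log)


def filter_low_variance(tensor: ResponseTensor, threshold: float) -> ResponseTensor:
    """Drop metabolites whose trajectory standard deviation (over all
    time points, pooled across individuals and diets) falls below
    ``threshold`` (concentration units, e.g. 1e-3 mM).

    Apply before standardization; afterwards every slice has unit
    variance and the filter is vacuous.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    stds = np.std(tensor.values.reshape(tensor.n_metabolites, -1), axis=1, ddof=1)
    keep = stds >= threshold
    if not keep.any():
        raise ValueError(f"variance filter at {threshold} removes every metabolite")
    values = tensor.values[keep]
    mets = tuple(m for m, k in zip(tensor.metabolite_ids, keep) if k)
    entry = {"op": "filter_low_variance", "params": {"threshold": threshold}}
    return replace(tensor, values=values, metabolite_ids=mets,
                   preprocessing_log=tensor.preprocessing_log + (entry,))


def logarithmic_indices(n_in: int, n_out: int) -> list[int]:
    """Endpoint-inclusive logarithmically spaced integer indices.

    Grid: ``exp(linspace(0, log(n_in), n_out)) - 1`` rounded to the
    integer grid; collisions are resolved by advancing to the next
    unused index, keeping the sequence strictly increasing.
    """
    if not 2 <= n_out <= n_in:
        raise ValueError(f"need 2 <= n_out <= T, got n_out={n_out}, T={n_in}")
    raw = np.exp(np.linspace(0.0, np.log(float(n_in)), n_out)) - 1.0
    indices: list[int] = []
    for r in raw:
        idx = int(round(r))
        if indices and idx <= indices[-1]:
            idx = indices[-1] + 1
        if idx > n_in - 1:
            raise ValueError("duplicate-advance overran the time grid")
        indices.append(idx)
    indices[-1] = n_in - 1
    return indices


def downsample_logarithmic(tensor: ResponseTensor, n_out: int) -> ResponseTensor:
    """Keep ``n_out`` logarithmically spaced time points (both endpoints
    always retained): dense sampling early after the meal, sparse late.
    """
    idx = logarithmic_indices(tensor.n_times, n_out)
    values = tensor.values[:, idx, :, :]
    times = tuple(tensor.time_points[i] for i in idx)
    entry = {"op": "downsample_logarithmic", "params": {"n_out": n_out}}
    return replace(tensor, values=values, time_points=times,
                   preprocessing_log=tensor.preprocessing_log + (entry,))


_REPLAY = {
    "subtract_baseline": lambda t, p: subtract_baseline(t),
    "standardize_per_diet": lambda t, p: standardize_per_diet(t, **p)[0],
    "filter_low_variance": lambda t, p: filter_low_variance(t, **p),
    "downsample_logarithmic": lambda t, p: downsample_logarithmic(t, **p),
}


def replay_log(raw: ResponseTensor, log: Sequence[dict]) -> ResponseTensor:
    """Re-apply a preprocessing log to a raw tensor, reproducing the
    processed tensor bit-for-bit."""
    out = raw
    for entry in log:
        try:
            fn = _REPLAY[entry["op"]]
        except KeyError:
            raise ValueError(f"unknown preprocessing op {entry['op']!r}") from None
        out = fn(out, dict(entry.get("params", {})))
    return out
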