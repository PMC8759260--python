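"""Linear CpG age predictors ("epigenetic clocks") and their diagnostics.

A clock is a named linear model over CpG beta values, optionally wrapped
in a transform: ``identity`` (the linear score is the predicted age in
years), ``horvath`` (the score lives on a piecewise log-linear scale and
is mapped back to years), or ``zhang`` (beta values are standardized
per sample across all supplied CpGs before scoring).

Besides prediction, this module computes prediction-error summaries,
cross-clock error concordance, the directed overlap of extreme
deviations, and replicate reliability (ICC).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

TRANSFORMS = ("identity", "horvath", "zhang")


@dataclass
class ClockModel:
    name: str
    intercept: float
    coefficients: dict[str, float]
    transform: str = "identity"
    adult_age: float = 20.0
    training_means: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("clock must have at least one coefficient")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "horvath" and not self.adult_age > 0:
            raise ValueError("adult_age must be positive for the horvath transform")

    @property
    def cpgs(self) -> list[str]:
        return list(self.coefficients)

    def __len__(self) -> int:
        return len(self.coefficients)


@dataclass
class AgePrediction:
    clock_name: str
    predicted: pd.Series          # years, indexed by sample
    n_missing_cpgs: pd.Series     # per sample, recorded even when zero


@dataclass
class PredictionErrorSummary:
    clock_name: str
    mae: float
    pearson_r: float
    errors: pd.Series             # predicted - chronological, years


def read_clock_model(path) -> ClockModel:
    """Read a clock coefficient CSV.

    Dialect: optional leading comment lines ``#transform=...``,
    ``#adult_age=...``, ``#name=...``; then a header ``id,coef`` with an
    optional third ``mean`` column; one row per CpG plus a required
    ``(Intercept)`` row.
    """
    transform = "identity"
    adult_age = 20.0
    name = None
    header = None
    coefficients: dict[str, float] = {}
    means: dict[str, float] = {}
    intercept = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key = key.strip().lower()
                if key == "transform":
                    transform = val.strip()
                elif key == "adult_age":
                    adult_age = float(val)
                elif key == "name":
                    name = val.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                header = [p.lower() for p in parts]
                if header[:2] != ["id", "coef"]:
                    raise ValueError(f"{path}: expected header 'id,coef', got {line!r}")
                continue
            cpg = parts[0]
            try:
                coef = float(parts[1])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: non-numeric weight at row {lineno}") from None
            if cpg == "(Intercept)":
                if intercept is not None:
                    raise ValueError(f"{path}: duplicate intercept row")
                intercept = coef
                continue
            if cpg in coefficients:
                raise ValueError(f"{path}: duplicate CpG ID {cpg!r}")
            coefficients[cpg] = coef
            if len(header) > 2 and len(parts) > 2 and parts[2] != "":
                means[cpg] = float(parts[2])
    if intercept is None:
        raise ValueError(f"{path}: missing '(Intercept)' row")
    return ClockModel(
        name=name or str(path), intercept=intercept, coefficients=coefficients,
        transform=transform, adult_age=adult_age,
        training_means=means or None)


def write_clock_model(model: ClockModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={model.name}\n")
        fh.write(f"#transform={model.transform}\n")
        if model.transform == "horvath":
            fh.write(f"#adult_age={model.adult_age!r}\n")
        has_means = model.training_means is not None
        fh.write("id,coef,mean\n" if has_means else "id,coef\n")
        fh.write(f"(Intercept),{float(model.intercept)!r}\n" if not has_means
                 else f"(Intercept),{float(model.intercept)!r},\n")
        for cpg, w in model.coefficients.items():
            if has_means:
                m = model.training_means.get(cpg, "")
                m = repr(float(m)) if m != "" else ""
                fh.write(f"{cpg},{float(w)!r},{m}\n")
            else:
                fh.write(f"{cpg},{float(w)!r}\n")


def zhang_standardize(beta: pd.DataFrame) -> pd.DataFrame:
    """Standardize each sample row to mean 0, SD 1 across all supplied CpGs.

    Uses the population SD (divisor n).  Raises on constant rows, naming
    the offending sample.
    """
    if beta.shape[1] < 2:
        raise ValueError("need at least 2 CpGs per sample to standardize")
    values = beta.values.astype(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant beta row for sample {beta.index[bad[0]]!r}")
    return pd.DataFrame((values - mean) / sd, index=beta.index, columns=beta.columns)


def horvath_forward_transform(age, adult_age: float = 20.0):
    """Piecewise log-linear age transform: log(age+1)-log(adult_age+1)
    below adult_age, (age-adult_age)/(adult_age+1) above."""
    age = np.asarray(age, dtype=float)
    return np.where(age <= adult_age,
                    np.log(age + 1.0) - math.log(adult_age + 1.0),
                    (age - adult_age) / (adult_age + 1.0))


def horvath_inverse_transform(x, adult_age: float = 20.0):
    """Inverse of :func:`horvath_forward_transform`; strictly increasing
    and continuous at x = 0 (which maps to adult_age)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x <= 0,
                   (adult_age + 1.0) * np.exp(x) - 1.0,
                   x * (adult_age + 1.0) + adult_age)
    return out if out.ndim else float(out)


def predict_age(model: ClockModel, beta: pd.DataFrame,
                max_missing_frac: float = 0.2) -> AgePrediction:
    """Apply a clock to a sample x CpG beta matrix.

    Missing clock CpGs (absent columns or NaN cells) are imputed from the
    clock's training means when available, else from the cohort mean of
    that CpG; entirely absent CpGs without a training mean cannot be
    imputed.  The number of imputed CpGs is recorded per sample.  More
    than ``max_missing_frac`` of the clock's CpGs missing is an error.
    """
    cpgs = model.cpgs
    present = [c for c in cpgs if c in beta.columns]
    absent = [c for c in cpgs if c not in beta.columns]
    if not present:
        raise ValueError(f"clock {model.name!r}: all clock CpGs missing from the matrix")
    if len(absent) / len(cpgs) > max_missing_frac:
        raise ValueError(
            f"clock {model.name!r}: {len(absent)}/{len(cpgs)} CpGs missing "
            f"(> {max_missing_frac:.0%} allowed)")
    tm = model.training_means or {}
    for c in absent:
        if c not in tm:
            raise ValueError(
                f"clock {model.name!r}: CpG {c!r} absent and no training mean available")

    if model.transform == "zhang":
        x = zhang_standardize(beta)
    else:
        x = beta
    mat = x.reindex(columns=cpgs).astype(float)
    n_missing = mat.isna().sum(axis=1)
    frac_missing = mat.isna().mean(axis=1)
    if (frac_missing > max_missing_frac).any():
        bad = frac_missing.idxmax()
        raise ValueError(
            f"clock {model.name!r}: sample {bad!r} missing {frac_missing.max():.0%} of clock CpGs")
    fill = {}
    for c in cpgs:
        if mat[c].isna().any():
            fill[c] = tm.get(c, float(mat[c].mean()))
            if not np.isfinite(fill[c]):
                raise ValueError(f"clock {model.name!r}: cannot impute CpG {c!r}")
    if fill:
        mat = mat.fillna(value=fill)

    w = np.array([model.coefficients[c] for c in cpgs])
    score = model.intercept + mat.values @ w
    if model.transform == "horvath":
        pred = horvath_inverse_transform(score, adult_age=model.adult_age)
    else:
        pred = score
    return AgePrediction(
        clock_name=model.name,
        predicted=pd.Series(np.asarray(pred, dtype=float), index=beta.index, name=model.name),
        n_missing_cpgs=n_missing)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def prediction_error_summary(pred: AgePrediction,
                             ages: pd.Series) -> PredictionErrorSummary:
    """MAE and Pearson r of a clock's predictions against chronological age."""
    common = pred.predicted.index.intersection(ages.index)
    if len(common) != len(pred.predicted) or len(common) != len(ages):
        raise ValueError("sample IDs of predictions and ages do not align")
    if len(common) < 3:
        raise ValueError("need at least 3 samples for a Pearson correlation")
    p = pred.predicted.loc[common].values.astype(float)
    a = ages.loc[common].values.astype(float)
    err = p - a
    return PredictionErrorSummary(
        clock_name=pred.clock_name,
        mae=float(np.mean(np.abs(err))),
        pearson_r=_pearson(p, a),
        errors=pd.Series(err, index=common, name=pred.clock_name))


def clock_concordance(summaries: Iterable[PredictionErrorSummary]) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-sample prediction errors."""
    summaries = list(summaries)
    names = [s.clock_name for s in summaries]
    n = len(names)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            common = summaries[i].errors.index.intersection(summaries[j].errors.index)
            r = _pearson(summaries[i].errors.loc[common].values,
                         summaries[j].errors.loc[common].values)
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


def extreme_deviation_overlap(errors_by_clock: Mapping[str, pd.Series] | pd.DataFrame,
                              threshold: float = 10.0) -> pd.DataFrame:
    """Directed overlap of extreme prediction errors.

    Entry (A, B) is the percentage of samples whose error under clock A
    is at least ``threshold`` years that also exceed the threshold under
    clock B.  Rows with no extreme sample for A are NaN (flagged
    undefined rather than zero).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(errors_by_clock, pd.DataFrame):
        errors = {c: errors_by_clock[c] for c in errors_by_clock.columns}
    else:
        errors = dict(errors_by_clock)
    if len(errors) < 2:
        raise ValueError("need at least 2 clocks")
    names = list(errors)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        ea = errors[a]
        extreme_a = ea.index[ea >= threshold]
        if len(extreme_a) == 0:
            continue
        for b in names:
            eb = errors[b].loc[extreme_a]
            out.loc[a, b] = 100.0 * float((eb >= threshold).mean())
    return out


def icc_2way_mean_rating(x: np.ndarray) -> float:
    """Shrout-Fleiss ICC(2,k): two-way random effects, absolute
    agreement, mean of k ratings, from the ANOVA decomposition."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 ratings")
    if np.isnan(x).any():
        raise ValueError("incomplete rating pairs")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def icc_absolute_agreement(first: pd.DataFrame, second: pd.DataFrame) -> pd.Series:
    """Per-CpG ICC(2,k=2) from two aligned replicate beta matrices
    (samples x CpGs; row i of each matrix is the same biological
    sample)."""
    if first.shape != second.shape:
        raise ValueError("replicate matrices must have identical shapes")
    if list(first.columns) != list(second.columns):
        raise ValueError("replicate matrices must share CpG columns")
    out = {}
    for c in first.columns:
        pairs = np.column_stack([first[c].values, second[c].values])
        out[c] = icc_2way_mean_rating(pairs)
    return pd.Series(out, name="icc")
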