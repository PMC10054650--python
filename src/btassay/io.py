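"""Reading, writing and report building.

The single interchange format is plain comma-separated text.  A bioassay
file has one row per well with the fixed header

    treatment,concentration_ng_ml,n_exposed,n_dead,replicate,is_control

and a mixture-definition file has the header

    mixture,component,proportion,treatment_ref

where ``treatment_ref`` names a treatment in a fit report.  Report tables
mirror the layout of classical LC50 tables (treatment, LC50, limits,
chi-square, df, slope with SE, intercept); numbers are rendered at 3
significant figures in reports while machine-readable sidecars keep full
precision.  Censored LC50s are always rendered with a ``>`` prefix and
never carry fabricated limits.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import mixtures as mx
from . import quantal as qt
from .errors import (
    DegenerateDataError,
    SchemaError,
    UnboundedLimitsError,
    UnknownTreatmentError,
)
from .types import BioassayObservation, LethalConcentration, MixtureComponent, QuantalFit

logger = logging.getLogger(__name__)

BIOASSAY_COLUMNS = [
    "treatment",
    "concentration_ng_ml",
    "n_exposed",
    "n_dead",
    "replicate",
    "is_control",
]
MIXTURE_COLUMNS = ["mixture", "component", "proportion", "treatment_ref"]
FIT_REPORT_COLUMNS = [
    "treatment",
    "lc50",
    "lower",
    "upper",
    "chi2",
    "df",
    "slope",
    "se_slope",
    "intercept",
]
MIX_REPORT_COLUMNS = [
    "treatment",
    "observed_lc50",
    "expected_lc50",
    "lower",
    "upper",
    "chi2",
    "df",
    "slope",
    "se_slope",
    "intercept",
    "synergism_factor",
    "interaction_class",
    "enabling_factor",
]

_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def _parse_bool(cell: str, row: int, column: str) -> bool:
    v = cell.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise SchemaError(f"row {row}, column {column!r}: not a boolean: {cell!r}",
                      row=row, column=column)


def read_bioassay(path: str | Path) -> list[BioassayObservation]:
    """Read and validate a bioassay CSV into observations.

    Raises :class:`SchemaError` naming the offending row and column on any
    violation; missing values are disallowed.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file")
    if list(df.columns) != BIOASSAY_COLUMNS:
        raise SchemaError(
            f"{path}: header must be {','.join(BIOASSAY_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    obs: list[BioassayObservation] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(BIOASSAY_COLUMNS, rec))
        for col, val in row.items():
            if val == "":
                raise SchemaError(f"row {i}, column {col!r}: missing value",
                                  row=i, column=col)
        parsed = {}
        for col, caster in (
            ("concentration_ng_ml", float),
            ("n_exposed", int),
            ("n_dead", float),
        ):
            try:
                parsed[col] = caster(row[col])
            except ValueError:
                raise SchemaError(
                    f"row {i}, column {col!r}: not numeric: {row[col]!r}",
                    row=i, column=col,
                )
        try:
            obs.append(
                BioassayObservation(
                    treatment=row["treatment"],
                    concentration=parsed["concentration_ng_ml"],
                    n_exposed=parsed["n_exposed"],
                    n_dead=parsed["n_dead"],
                    replicate=row["replicate"],
                    is_control=_parse_bool(row["is_control"], i, "is_control"),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}", row=i)
    return obs


def write_bioassay(observations: Iterable[BioassayObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "treatment": o.treatment,
                "concentration_ng_ml": repr(o.concentration),
                "n_exposed": o.n_exposed,
                "n_dead": o.n_dead if o.n_dead % 1 else int(o.n_dead),
                "replicate": o.replicate,
                "is_control": str(o.is_control).lower(),
            }
            for o in observations
        ],
        columns=BIOASSAY_COLUMNS,
    )
    df.to_csv(path, index=False)


def apply_abbott(
    observations: Sequence[BioassayObservation],
) -> list[BioassayObservation]:
    """Abbott-correct treated wells per replicate against their controls.

    Control baseline lookup order: controls sharing (treatment, replicate),
    then controls sharing the replicate, then all controls pooled; zero
    when no controls exist.  Corrected deaths are n * corrected proportion
    and may be fractional.
    """
    controls = [o for o in observations if o.is_control]

    def baseline(treatment: str, replicate: str) -> float:
        for pool in (
            [c for c in controls if c.treatment == treatment and c.replicate == replicate],
            [c for c in controls if c.replicate == replicate],
            controls,
        ):
            if pool:
                n = sum(c.n_exposed for c in pool)
                return sum(c.n_dead for c in pool) / n
        return 0.0

    out = []
    for o in observations:
        if o.is_control:
            continue
        p_c = baseline(o.treatment, o.replicate)
        p_corr = qt.abbott_correct(o.mortality, p_c)
        out.append(
            BioassayObservation(
                treatment=o.treatment,
                concentration=o.concentration,
                n_exposed=o.n_exposed,
                n_dead=p_corr * o.n_exposed,
                replicate=o.replicate,
            )
        )
    return out


def fit_treatments(
    observations: Sequence[BioassayObservation],
    *,
    link: str = "logit",
    ci_method: str = "fieller",
    confidence: float = 0.95,
    activity_threshold: float = 0.10,
) -> tuple[pd.DataFrame, dict[str, QuantalFit]]:
    """Fit every treatment and assemble a full-precision report table.

    Treatments whose response is degenerate (no signal) get a censored LC50
    row: '> top dose' when the high-dose corrected mortality is below the
    activity threshold, '< bottom dose' when mortality saturates at every
    dose.  Returns (report frame, treatment -> QuantalFit for converged fits).
    """
    rows: list[dict] = []
    fits: dict[str, QuantalFit] = {}
    treatments: dict[str, list[BioassayObservation]] = {}
    for o in observations:
        treatments.setdefault(o.treatment, []).append(o)

    for name, group in treatments.items():
        if all(o.is_control for o in group):
            continue
        corrected = apply_abbott(
            group + [o for o in observations if o.is_control and o.treatment != name]
        )
        corrected = [o for o in corrected if o.treatment == name]
        row: dict = {c: math.nan for c in FIT_REPORT_COLUMNS}
        row["treatment"] = name
        try:
            fit = qt.fit_quantal(corrected, link=link)
            fits[name] = fit
            try:
                lc = qt.confidence_limits(fit, 0.5, method=ci_method, confidence=confidence)
                row.update(lc50=lc.estimate, lower=lc.lower, upper=lc.upper)
            except UnboundedLimitsError as exc:
                row["lc50"] = qt.lc_p(fit, 0.5).estimate
                logger.warning("treatment %r: %s; limits omitted", name, exc)
                warnings.warn(f"treatment {name!r}: {exc}; limits omitted", stacklevel=2)
            row.update(
                chi2=fit.chi2, df=fit.df, slope=fit.slope,
                se_slope=fit.slope_se, intercept=fit.intercept,
            )
        except DegenerateDataError as exc:
            doses, n, y = qt.pool_observations(corrected)
            screen = qt.activity_screen(
                dict(zip(doses, y / n)), float(doses[-1]), activity_threshold
            )
            if screen.verdict == "non_active":
                row["lc50"] = screen.lc50
            elif (y / n)[0] >= 0.5:
                row["lc50"] = LethalConcentration.censored_below(float(doses[0]))
            logger.warning("treatment %r: degenerate response (%s); censored row emitted",
                           name, exc)
            warnings.warn(f"treatment {name!r}: {exc}; reporting a censored LC50",
                          stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows, columns=FIT_REPORT_COLUMNS), fits


def format_value(value, sig: int = 3) -> str:
    """Render one report cell: 3 significant figures, '>bound' for censored."""
    if isinstance(value, LethalConcentration):
        return str(value)
    if isinstance(value, str):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, (int, np.integer)) or (isinstance(value, float) and value == int(value) and abs(value) < 1e6):
        if float(value).is_integer() and abs(value) < 100:
            return str(int(value))
    return f"{value:.{sig}g}"


def render_report(df: pd.DataFrame, sig: int = 3) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in ("treatment", "interaction_class"):
            continue
        out[col] = [format_value(v, sig) for v in out[col]]
    return out


def write_report(df: pd.DataFrame, path: str | Path, *, meta: Mapping | None = None,
                 sig: int = 3) -> None:
    """Write a rendered report plus a full-precision JSON sidecar
    (<path>.meta.json) echoing the run configuration."""
    path = Path(path)
    render_report(df, sig).to_csv(path, index=False)
    sidecar = {
        "config": dict(meta or {}),
        "results": [
            {k: (str(v) if isinstance(v, LethalConcentration) else v)
             for k, v in rec.items() if not (isinstance(v, float) and math.isnan(v))}
            for rec in df.to_dict(orient="records")
        ],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2, default=float))


def parse_lc50_cell(cell: str) -> LethalConcentration | None:
    """Parse a report LC50 cell: a number, '>bound'/'<bound', or empty."""
    cell = str(cell).strip()
    if not cell or cell.lower() == "nan":
        return None
    if cell.startswith(">"):
        return LethalConcentration.censored_above(float(cell[1:]))
    if cell.startswith("<"):
        return LethalConcentration.censored_below(float(cell[1:]))
    return LethalConcentration.point(float(cell))


def read_fit_report(path: str | Path) -> pd.DataFrame:
    """Read a fit report back; the lc50 column becomes LethalConcentration
    objects (None for blank rows)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file")
    missing = [c for c in FIT_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: fit report missing columns {missing}")
    df["lc50"] = [parse_lc50_cell(c) for c in df["lc50"]]
    for col in FIT_REPORT_COLUMNS[2:]:
        df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    return df


def read_mixture_definition(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file")
    if list(df.columns) != MIXTURE_COLUMNS:
        raise SchemaError(
            f"{path}: header must be {','.join(MIXTURE_COLUMNS)}, got {','.join(df.columns)}"
        )
    try:
        df["proportion"] = df["proportion"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric proportion ({exc})")
    return df


def mix_report(
    fit_report: pd.DataFrame,
    mixture_def: pd.DataFrame,
    *,
    synergy_threshold: float = 2.0,
    antagonism_threshold: float = 0.5,
) -> pd.DataFrame:
    """Build the interaction report from a fit report and mixture definitions.

    Each mixture label must itself appear as a treatment in the fit report
    (its observed LC50 and fit statistics); each component's
    ``treatment_ref`` must resolve to a fitted or censored treatment.
    """
    by_treatment = {rec["treatment"]: rec for rec in fit_report.to_dict(orient="records")}
    rows = []
    for mixture, group in mixture_def.groupby("mixture", sort=False):
        if mixture not in by_treatment:
            raise UnknownTreatmentError(f"mixture {mixture!r} has no row in the fit report")
        mix_row = by_treatment[mixture]
        mix_lc = mix_row["lc50"]
        components = []
        for rec in group.to_dict(orient="records"):
            ref = rec["treatment_ref"]
            if ref not in by_treatment:
                raise UnknownTreatmentError(
                    f"mixture {mixture!r}: component reference {ref!r} not in fit report"
                )
            lc = by_treatment[ref]["lc50"]
            if lc is None:
                raise UnknownTreatmentError(
                    f"mixture {mixture!r}: component {ref!r} has no usable LC50"
                )
            components.append(
                MixtureComponent(label=rec["component"], proportion=rec["proportion"], lc50=lc)
            )
        if mix_lc is None or mix_lc.censored:
            raise UnknownTreatmentError(
                f"mixture {mixture!r}: no finite observed LC50 in the fit report"
            )
        assessment = mx.assess_mixture(
            components,
            mix_lc.estimate,
            synergy_threshold=synergy_threshold,
            antagonism_threshold=antagonism_threshold,
        )
        rows.append(
            {
                "treatment": mixture,
                "observed_lc50": assessment.observed_lc50,
                "expected_lc50": assessment.expected_lc50,
                "lower": mix_row["lower"],
                "upper": mix_row["upper"],
                "chi2": mix_row["chi2"],
                "df": mix_row["df"],
                "slope": mix_row["slope"],
                "se_slope": mix_row["se_slope"],
                "intercept": mix_row["intercept"],
                "synergism_factor": assessment.synergism_factor,
                "interaction_class": assessment.interaction_class,
                "enabling_factor": assessment.enabling_factor
                if assessment.enabling_factor is not None
                else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=MIX_REPORT_COLUMNS)
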