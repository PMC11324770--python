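"""Dose-response analysis of the junction endpoint.

Per-well metrics are normalized to vehicle (DMSO) controls on the same
plate, an IC50 is estimated for each compound from the fold-change of
junction area per cell, and compounds are classified POSITIVE (established
IC50 within the tested range) or NEGATIVE.  Predictivity against an
annotated truth table is summarized with Cooper statistics (sensitivity,
specificity, accuracy), and per-concentration group differences with a
pooled-variance two-sample Student's t test.

The default IC50 estimator follows a linear-regression reading: response is
regressed on log10(concentration) over the points bracketing the 0.5
crossing and the crossing concentration is solved for.  A 4-parameter
logistic alternative is available (``method="fourpl"``).  An IC50 is
"established" only when the normalized response reaches <= 0.5 somewhere in
the tested range — compounds with only minor effects at the top
concentration stay NOT_ESTABLISHED.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NOT_ESTABLISHED",
    "DoseResponseFit",
    "CooperStats",
    "normalize_to_vehicle",
    "fit_ic50",
    "classify_compound",
    "cooper_statistics",
    "per_concentration_test",
    "load_validation_set",
    "predict_response",
]

NOT_ESTABLISHED = "NOT_ESTABLISHED"


@dataclasses.dataclass
class DoseResponseFit:
    compound_id: str
    concentrations_um: np.ndarray
    responses: np.ndarray
    viability_responses: np.ndarray | None
    ic50_um: float | None  # None == NOT_ESTABLISHED
    method: str
    slope: float = float("nan")
    residual_sd: float = float("nan")
    multiple_crossings: bool = False
    #: 4PL parameters (top, bottom, ic50, hill) when method == "fourpl"
    params: tuple | None = None

    @property
    def established(self) -> bool:
        return self.ic50_um is not None


@dataclasses.dataclass
class CooperStats:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else None


def normalize_to_vehicle(well_table: pd.DataFrame) -> pd.DataFrame:
    """Fold change over the vehicle controls of the same plate.

    Expects the per-well metrics schema from :mod:`occlusim.quantify`.
    Replicate wells at the same concentration on the same plate are
    averaged.  Returns one row per (plate, compound, concentration) with
    ``response`` (junction area per cell fold change) and
    ``viability_response`` (nuclei count fold change).
    """
    rows = []
    for plate, grp in well_table.groupby("plate", sort=False):
        veh = grp[grp["role"] == "vehicle"]
        if veh.empty:
            raise ValueError(f"plate {plate!r} has no vehicle wells")
        veh_junction = veh["junction_area_per_cell_um2"].mean()
        veh_count = veh["mean_nuclei_count"].mean()
        if veh_junction == 0 or veh_count == 0:
            raise ValueError(f"plate {plate!r}: vehicle mean is zero")
        treated = grp[grp["role"] == "treated"]
        for (compound, conc), sub in treated.groupby(
                ["compound", "concentration_um"], sort=True):
            rows.append({
                "plate": plate, "compound": compound,
                "concentration_um": float(conc),
                "response": sub["junction_area_per_cell_um2"].mean()
                / veh_junction,
                "viability_response": sub["mean_nuclei_count"].mean()
                / veh_count,
                "n_wells": len(sub),
            })
    return pd.DataFrame(rows)


def _loglinear_ic50(conc: np.ndarray, resp: np.ndarray,
                    min_response_le: float) -> tuple[float | None, float, float, bool]:
    """Crossing of the ``min_response_le`` level on a response-vs-log10(c)
    regression restricted to the points bracketing the crossing.

    Returns (ic50 or None, slope, residual sd, multiple-crossings flag).
    Works on per-concentration mean responses; the lowest-concentration
    crossing wins when the series is non-monotone.
    """
    order = np.argsort(conc)
    c = conc[order]
    # mean response per unique concentration (pooled replicates)
    uc, inv = np.unique(c, return_inverse=True)
    means = np.bincount(inv, weights=resp[order]) / np.bincount(inv)
    if means.min() > min_response_le:
        return None, float("nan"), float("nan"), False

    above = means > min_response_le
    crossings = [i for i in range(1, len(uc)) if above[i - 1] != above[i]]
    multiple = len(crossings) > 1
    if not crossings:
        # below the level everywhere: anchor at the lowest concentrations
        idx = list(range(min(3, len(uc))))
    else:
        i = crossings[0]
        idx = [i - 1, i]
        # extend to >= 3 points, preferring the bracketing neighbourhood
        k = 1
        while len(idx) < 3 and (i - 1 - k >= 0 or i + k < len(uc)):
            if i + k < len(uc):
                idx.append(i + k)
            if len(idx) < 3 and i - 1 - k >= 0:
                idx.insert(0, i - 1 - k)
            k += 1
    idx = sorted(set(idx))
    x = np.log10(uc[idx])
    y = means[idx]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    resid_sd = float(np.std(resid, ddof=min(len(y) - 1, 2))) \
        if len(y) > 2 else 0.0
    if slope == 0:
        return None, 0.0, resid_sd, multiple
    log_ic50 = (min_response_le - intercept) / slope
    if crossings:
        i = crossings[0]
        lo, hi = np.log10(uc[i - 1]), np.log10(uc[i])
        if not lo <= log_ic50 <= hi:
            # non-monotone neighbourhood pulled the regression outside the
            # bracketing interval: interpolate the crossing directly
            y0, y1 = means[i - 1], means[i]
            log_ic50 = lo + (min_response_le - y0) / (y1 - y0) * (hi - lo)
    ic50 = 10.0 ** log_ic50
    # established IC50 is reported within the tested range
    ic50 = float(np.clip(ic50, uc.min(), uc.max()))
    return ic50, float(slope), resid_sd, multiple


def _fourpl(c: np.ndarray, top: float, bottom: float, ic50: float,
            hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def _fourpl_ic50(conc: np.ndarray, resp: np.ndarray,
                 min_response_le: float) -> tuple[float | None, tuple | None, float]:
    if resp.min() > min_response_le:
        return None, None, float("nan")
    p0 = (1.0, 0.0, float(np.sqrt(conc.min() * conc.max())), 1.0)
    bounds = ([0.7, 0.0, conc.min() / 100, 0.2],
              [1.3, 0.5, conc.max() * 100, 8.0])
    try:
        popt, _ = optimize.curve_fit(_fourpl, conc, resp, p0=p0,
                                     bounds=bounds, maxfev=20000)
    except RuntimeError:
        return None, None, float("nan")
    resid = resp - _fourpl(conc, *popt)
    resid_sd = float(np.std(resid, ddof=1)) if len(resp) > 1 else 0.0
    ic50 = float(np.clip(popt[2], conc.min(), conc.max()))
    return ic50, tuple(float(v) for v in popt), resid_sd


def fit_ic50(concentrations_um: np.ndarray,
             responses: np.ndarray,
             viability_responses: np.ndarray | None = None,
             compound_id: str = "CMPD",
             method: str = "loglinear",
             min_response_le: float = 0.5) -> DoseResponseFit:
    """Estimate the IC50 of the normalized junction endpoint.

    ``concentrations_um``/``responses`` may contain replicate points (all
    are pooled).  The fit is NOT_ESTABLISHED when no response reaches
    ``min_response_le`` within the tested range.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must align")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(conc <= 0) or not np.all(np.isfinite(resp)):
        raise ValueError("concentrations must be positive, responses finite")

    if method == "loglinear":
        ic50, slope, resid_sd, multiple = _loglinear_ic50(
            conc, resp, min_response_le)
        params = None
    elif method == "fourpl":
        ic50, params, resid_sd = _fourpl_ic50(conc, resp, min_response_le)
        slope = float("nan") if params is None else -params[3]
        multiple = False
    else:
        raise ValueError(f"unknown method {method!r}")
    return DoseResponseFit(compound_id, conc, resp, viability_responses,
                           ic50, method, slope, resid_sd, multiple, params)


def predict_response(fit: DoseResponseFit, conc_um: float) -> float:
    """Fitted response at a concentration (used to map exposures onto the
    in vitro curve).  For loglinear fits a unit-top/zero-bottom logistic at
    the established IC50 is used as the smooth curve through the data."""
    if fit.method == "fourpl" and fit.params is not None:
        return float(_fourpl(np.asarray([conc_um]), *fit.params)[0])
    if fit.ic50_um is None:
        raise ValueError("cannot predict from a NOT_ESTABLISHED fit")
    return float(1.0 / (1.0 + conc_um / fit.ic50_um))


def classify_compound(fit: DoseResponseFit) -> str:
    """POSITIVE iff the IC50 was established within the tested range."""
    return "POSITIVE" if fit.established else "NEGATIVE"


def cooper_statistics(predictions: pd.DataFrame,
                      truth: pd.DataFrame) -> CooperStats:
    """Predictivity counts.

    ``predictions``: columns (compound, prediction POSITIVE/NEGATIVE);
    ``truth``: columns (compound, risk) with risk truthy for a known
    respiratory safety risk.  Compound sets must match.
    """
    p = predictions.set_index("compound")["prediction"]
    t = truth.set_index("compound")["risk"]
    if set(p.index) != set(t.index):
        raise ValueError("prediction and truth compound sets differ")
    tp = fn = tn = fp = 0
    for compound in t.index:
        positive = p[compound] == "POSITIVE"
        risky = bool(t[compound])
        if risky and positive:
            tp += 1
        elif risky:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    return CooperStats(tp, fn, tn, fp)


def per_concentration_test(group1: pd.DataFrame,
                           group2: pd.DataFrame) -> pd.DataFrame:
    """Two-sided pooled-variance Student's t test at each concentration.

    Each input has columns (concentration_um, response); >= 2 values per
    group per concentration are required.  The t statistic is computed from
    the textbook pooled-variance formula; p comes from the t distribution
    with n1 + n2 - 2 degrees of freedom.  p-values are NOT adjusted for the
    multiplicity across concentrations (flagged in the output).
    """
    rows = []
    concs = sorted(set(group1["concentration_um"]).intersection(
        group2["concentration_um"]))
    for conc in concs:
        x1 = group1.loc[group1["concentration_um"] == conc,
                        "response"].to_numpy(dtype=float)
        x2 = group2.loc[group2["concentration_um"] == conc,
                        "response"].to_numpy(dtype=float)
        n1, n2 = len(x1), len(x2)
        if n1 < 2 or n2 < 2:
            raise ValueError(f"need >= 2 values per group at {conc} uM")
        df = n1 + n2 - 2
        sp2 = (((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df)
        diff = x1.mean() - x2.mean()
        zero_var = sp2 == 0
        if zero_var:
            t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            p = 2.0 * stats.t.sf(abs(t), df)
        rows.append({"concentration_um": conc, "t": t, "p": p, "df": df,
                     "zero_variance": zero_var, "p_adjusted": False})
    return pd.DataFrame(rows)


def load_validation_set() -> pd.DataFrame:
    """The 19-compound assay validation set shipped with the package:
    compound, mechanism, respiratory risk (bool) and printed IC50 (NaN where
    no curve could be established)."""
    ref = importlib.resources.files("occlusim.data") / "validation_set.csv"
    with importlib.resources.as_file(ref) as path:
        tbl = pd.read_csv(path, na_values=["NA"])
    tbl["respiratory_risk"] = tbl["respiratory_risk"].map(
        {"yes": True, "no": False})
    if tbl["respiratory_risk"].isna().any():
        raise ValueError("risk column must be yes/no")
    return tbl
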