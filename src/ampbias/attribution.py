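"""Attribute amplification efficiencies to template characteristics.

Estimated per-cycle log-ratio efficiencies (alpha) are modelled as a linear
function of reference-relative primer-template mismatch counts, amplicon GC
content, and amplicon length:

    alpha_ijk = b1k * mm_ij + b2k * gc_ij + b3 * len_ij + eps_ijk

for species i, marker j, Taq polymerase k, where mismatch and GC effects
interact with the Taq (b1k, b2k vary by polymerase) and eps ~ N(0, sigma).
All predictors are expressed relative to the reference species for the same
marker (a species with 3 mismatches vs. a reference with 1 enters as 2),
matching the compositional log-ratio scale of alpha itself; consequently
the model carries no global intercept — the reference species anchors zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calibration import EfficiencyEstimate, estimates_to_frame

__all__ = [
    "DEFAULT_FORMULA",
    "AttributionFit",
    "build_relative_design",
    "join_design",
    "fit_attribution",
    "compare_models",
]

#: Terms: a base predictor in {mm, gc, len}, optionally ":taq" for a
#: per-polymerase coefficient.
DEFAULT_FORMULA: tuple[str, ...] = ("mm:taq", "gc:taq", "len")

_BASE_COLUMN = {"mm": "mm_rel", "gc": "gc_rel", "len": "len_rel"}


@dataclass
class AttributionFit:
    """An ordinary-least-squares fit of the efficiency-attribution model."""

    coefficients: pd.DataFrame  # term, taq, estimate, lo, hi
    residual_sd: float
    r_squared: float
    n_obs: int
    formula: tuple[str, ...]
    aicc: float

    def coefficient(self, term: str, taq: str | None = None) -> float:
        sel = self.coefficients["term"] == term
        if taq is not None:
            sel &= self.coefficients["taq"] == taq
        vals = self.coefficients.loc[sel, "estimate"]
        if len(vals) != 1:
            raise KeyError(f"no unique coefficient for ({term}, {taq})")
        return float(vals.iloc[0])


def build_relative_design(
    profiles: pd.DataFrame,
    reference_species: str,
) -> pd.DataFrame:
    """Reference-relative predictors per (species, marker).

    ``profiles`` needs columns species, marker, mm_total, gc, length_bp
    (the output of :func:`ampbias.insilico_pcr.profile_panel`).  For each
    marker the reference species' values are subtracted, so the reference
    row is identically zero.  The operation is idempotent: applying it to
    its own output (whose reference rows are zero) changes nothing.
    """
    need = {"species", "marker", "mm_total", "gc", "length_bp"}
    missing = need - set(profiles.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    out_rows = []
    for marker, sub in profiles.groupby("marker", sort=False):
        ref = sub[sub["species"] == reference_species]
        if ref.empty:
            raise ValueError(
                f"reference species {reference_species!r} not profiled for marker {marker!r}"
            )
        ref = ref.iloc[0]
        for r in sub.itertuples():
            out_rows.append(
                {
                    "species": r.species,
                    "marker": marker,
                    "mm_rel": float(r.mm_total - ref.mm_total),
                    "gc_rel": float(r.gc - ref.gc),
                    "len_rel": float(r.length_bp - ref.length_bp),
                }
            )
    return pd.DataFrame(out_rows)


def join_design(
    alphas: Sequence[EfficiencyEstimate] | pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Join efficiency estimates with relative predictors on (species, marker)."""
    adf = alphas if isinstance(alphas, pd.DataFrame) else estimates_to_frame(alphas)
    merged = adf.merge(
        design, left_on=["species", "marker_name"], right_on=["species", "marker"],
        how="inner", validate="many_to_one",
    )
    if merged.empty:
        raise ValueError("efficiency table and design share no (species, marker) rows")
    return merged


def _design_matrix(data: pd.DataFrame, formula: Sequence[str]):
    """Build the no-intercept design matrix for the given terms."""
    cols, names = [], []
    taqs = sorted(data["taq"].unique())
    for term in formula:
        if term.endswith(":taq"):
            base = term[:-4]
            col = _BASE_COLUMN.get(base)
            if col is None:
                raise ValueError(f"unknown term {term!r}")
            if len(taqs) < 2 and len(formula) > 1:
                pass  # a single Taq level degenerates to a plain slope
            for taq in taqs:
                cols.append(data[col].values * (data["taq"] == taq).values)
                names.append(f"{base}[{taq}]")
        else:
            col = _BASE_COLUMN.get(term)
            if col is None:
                raise ValueError(f"unknown term {term!r}")
            cols.append(data[col].values.astype(float))
            names.append(term)
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names


def _aicc(llf: float, k: int, n: int) -> float:
    aic = -2 * llf + 2 * k
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_attribution(
    alphas: Sequence[EfficiencyEstimate] | pd.DataFrame,
    design: pd.DataFrame,
    formula: Sequence[str] = DEFAULT_FORMULA,
    ci_level: float = 0.95,
    include_reference_rows: bool = False,
) -> AttributionFit:
    """OLS fit of alpha on reference-relative predictors, no intercept.

    R² is computed as 1 - SS_res/SS_tot on the fitted alpha values.
    Reference-species rows (zero response, zero predictors by construction)
    are excluded by default: they carry no information and would deflate
    the residual variance.
    """
    data = join_design(alphas, design)
    if not include_reference_rows:
        data = data[data["species"] != data["reference"]]
    if data.empty:
        raise ValueError("no non-reference rows to fit")
    y = data["alpha_hat"].values.astype(float)
    X, names = _design_matrix(data, formula)
    if X.shape[1] == 0:
        raise ValueError("empty model formula")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in range(len(names))
                   if i >= len(diag) or diag[i] < 1e-10 * max(diag.max(), 1.0)]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased or names}")
    res = sm.OLS(y, X).fit()
    resid = y - res.fittedvalues
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(y) - X.shape[1], 1)
    sigma = float(np.sqrt(ss_res / dof))
    ci = res.conf_int(alpha=1 - ci_level)
    rows = []
    for i, name in enumerate(names):
        base, taq = (name.split("[")[0], name.split("[")[1][:-1]) if "[" in name else (name, "")
        rows.append(
            {
                "term": base,
                "taq": taq,
                "estimate": float(res.params[i]),
                "lo": float(ci[i][0]),
                "hi": float(ci[i][1]),
            }
        )
    return AttributionFit(
        coefficients=pd.DataFrame(rows),
        residual_sd=sigma,
        r_squared=float(r2),
        n_obs=len(y),
        formula=tuple(formula),
        aicc=_aicc(res.llf, X.shape[1] + 1, len(y)),
    )


def compare_models(
    candidates: Sequence[Sequence[str]],
    alphas: Sequence[EfficiencyEstimate] | pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Rank candidate formulas by small-sample-corrected AIC.

    Ties (within 1e-9) are broken in favour of fewer parameters.  A
    candidate that fails to fit is retained in the table with
    ``failed=True`` and ranked last.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate formulas")
    rows = []
    for formula in candidates:
        entry = {"formula": "+".join(formula), "n_terms": len(formula)}
        try:
            fit = fit_attribution(alphas, design, formula=formula)
            entry |= {
                "aicc": fit.aicc,
                "r_squared": fit.r_squared,
                "n_params": len(fit.coefficients),
                "failed": False,
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            entry |= {
                "aicc": float("inf"),
                "r_squared": float("nan"),
                "n_params": -1,
                "failed": True,
                "error": str(exc),
            }
        rows.append(entry)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["failed", "aicc", "n_params"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
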