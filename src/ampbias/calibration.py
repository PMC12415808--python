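"""Amplification-efficiency calibration.

The forward model for one PCR: a species starting from ``c_i`` template
copies and amplifying with per-cycle efficiency ``a_i`` yields

    A_i = c_i (1 + a_i)^N

amplicons after N cycles.  Read data are compositional, so only ratios are
identifiable; we work with the per-cycle log-ratio efficiency

    alpha_i = log(1 + a_i) - log(1 + a_ref)

relative to a named reference species (alpha_ref = 0 by construction).
Expected read proportions are then a softmax over ``log c_i + N alpha_i``.
Mock communities with known template amounts let us invert this map and
estimate alpha per species; those estimates calibrate field samples whose
template amounts are unknown.

Two estimators are provided: a closed-form per-replicate log-ratio (point)
estimator, and a multinomial maximum-a-posteriori fit with Laplace
intervals (bayes).  Efficiencies are assumed constant across community
compositions, and estimates are only transferable within the same
marker-Taq combination; :func:`calibrate_sample` enforces this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import softmax

from .quantification import MockCommunity

__all__ = [
    "ForwardModelInput",
    "ReadTable",
    "EfficiencyEstimate",
    "CalibrationResult",
    "forward_read_proportions",
    "simulate_read_counts",
    "estimate_efficiencies",
    "estimate_efficiencies_by_group",
    "calibrate_sample",
    "summarize_bias",
    "estimates_to_frame",
    "frame_to_estimates",
]

DEFAULT_N_CYCLES = 35
DEFAULT_KAPPA = 0.5


@dataclass
class ForwardModelInput:
    """Inputs to the forward proportion model for one reaction."""

    species: list[str]
    log_template: np.ndarray
    alpha: np.ndarray
    n_cycles: int = DEFAULT_N_CYCLES
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.log_template = np.asarray(self.log_template, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.log_template.shape != self.alpha.shape:
            raise ValueError("log_template and alpha must be conformable")
        if len(self.species) != self.log_template.size:
            raise ValueError("species list and vectors must be conformable")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


class ReadTable:
    """Species x sample integer read counts plus per-sample PCR metadata.

    ``counts`` is a DataFrame (rows: species, columns: sample ids);
    ``metadata`` is a DataFrame indexed by sample id with columns
    ``marker``, ``taq``, ``bsa`` (bool), ``cycling``, ``replicate``.
    """

    REQUIRED_META = ("marker", "taq", "bsa", "cycling", "replicate")

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        counts = counts.copy()
        if (counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("read counts must be integers")
        counts = counts.astype(np.int64)
        depths = counts.sum(axis=0)
        if (depths <= 0).any():
            bad = list(depths.index[depths <= 0])
            raise ValueError(f"samples with zero depth: {bad}")
        missing_samples = set(counts.columns) - set(metadata.index)
        if missing_samples:
            raise ValueError(f"samples missing metadata: {sorted(missing_samples)}")
        missing_cols = set(self.REQUIRED_META) - set(metadata.columns)
        if missing_cols:
            raise ValueError(f"metadata missing columns: {sorted(missing_cols)}")
        self.counts = counts
        self.metadata = metadata.loc[counts.columns].copy()

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ReadTable":
        return ReadTable(self.counts[list(sample_ids)], self.metadata)

    def groupby_condition(self, keys=("marker", "taq")):
        """Yield ((key values), ReadTable of that condition's samples)."""
        for key, sub in self.metadata.groupby(list(keys), sort=True):
            yield key, self.subset_samples(list(sub.index))

    def to_tsv(self, counts_path, metadata_path) -> None:
        self.counts.rename_axis("species").to_csv(counts_path, sep="\t")
        self.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "ReadTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        if "bsa" in meta.columns:
            meta["bsa"] = meta["bsa"].astype(bool)
        return cls(counts, meta)


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Per-cycle log-ratio amplification efficiency for one species."""

    species: str
    marker_name: str
    taq: str
    alpha_hat: float
    lo: float
    hi: float
    reference_species: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha_hat):
            raise ValueError("alpha_hat must be finite")


@dataclass
class CalibrationResult:
    """A calibrated (pre-PCR) composition with sampling-based intervals."""

    species: list[str]
    proportions: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


def forward_read_proportions(
    model: ForwardModelInput | None = None,
    *,
    log_template: Sequence[float] | None = None,
    alpha: Sequence[float] | None = None,
    n_cycles: int = DEFAULT_N_CYCLES,
) -> np.ndarray:
    """Expected read proportions pi_i ∝ exp(log c_i + N alpha_i).

    Numerically stabilized softmax; invariant under alpha -> alpha + delta
    and c -> k c (compositional shift invariance).
    """
    if model is not None:
        log_template, alpha, n_cycles = model.log_template, model.alpha, model.n_cycles
    lt = np.asarray(log_template, dtype=float)
    al = np.asarray(alpha, dtype=float)
    if lt.shape != al.shape:
        raise ValueError("log_template and alpha must be conformable")
    z = lt + n_cycles * al
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite forward-model inputs")
    return softmax(z)


def simulate_read_counts(
    proportions: Sequence[float],
    depth: int,
    overdispersion: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a read-count vector at the given sequencing depth.

    ``overdispersion == 0`` gives multinomial sampling; otherwise a
    Dirichlet-multinomial with concentration ``proportions/overdispersion``
    (larger values -> noisier replicate compositions).
    """
    pi = np.asarray(proportions, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if overdispersion < 0:
        raise ValueError("overdispersion must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if overdispersion == 0:
        return rng.multinomial(depth, pi)
    conc = pi / overdispersion
    # Dirichlet draws with zero concentration are degenerate at zero.
    p = np.zeros_like(pi)
    pos = conc > 0
    p[pos] = rng.dirichlet(conc[pos])
    return rng.multinomial(depth, p)


def _check_reads_vs_mock(mock: MockCommunity, reads: ReadTable) -> np.ndarray:
    mock_species = mock.species
    missing = set(mock_species) - set(reads.species)
    if missing:
        raise ValueError(f"mock species absent from read table: {sorted(missing)}")
    return reads.counts.loc[mock_species].values  # species x samples


def _condition_of(reads: ReadTable) -> tuple[str, str]:
    markers = reads.metadata["marker"].unique()
    taqs = reads.metadata["taq"].unique()
    if len(markers) != 1 or len(taqs) != 1:
        raise ValueError(
            "replicates span multiple marker-Taq combinations; "
            "estimate each combination separately"
        )
    return str(markers[0]), str(taqs[0])


def estimate_efficiencies(
    mock: MockCommunity,
    reads: ReadTable,
    n_cycles: int = DEFAULT_N_CYCLES,
    reference_species: str | None = None,
    method: str = "point",
    kappa: float = DEFAULT_KAPPA,
    prior_sd: float = 0.5,
    ci_level: float = 0.95,
) -> list[EfficiencyEstimate]:
    """Estimate per-species alpha from mock-community replicates.

    All samples in ``reads`` must be technical replicates of ``mock`` under
    one marker-Taq combination.

    ``point``: per replicate,
    ``alpha_i = [log((r_i+kappa)/(r_ref+kappa)) - log(c_i/c_ref)] / N``,
    averaged over replicates with a normal interval on the replicate mean.
    ``bayes``: multinomial MAP over alpha (reference fixed at 0) with a
    N(0, prior_sd) prior and Laplace (inverse-Hessian) intervals.
    """
    if reference_species is None:
        raise ValueError("reference_species must be named explicitly")
    species = mock.species
    if reference_species not in species:
        raise ValueError(f"reference species {reference_species!r} not in mock")
    marker, taq = _condition_of(reads)
    counts = _check_reads_vs_mock(mock, reads)  # S x R
    ref = species.index(reference_species)
    if np.any(counts[ref] == 0) and kappa == 0 and method == "point":
        raise ValueError("reference species has zero counts and kappa=0")
    log_c = np.log(mock.expected_proportions)
    zcrit = float(-_norm_ppf((1 - ci_level) / 2))

    if method == "point":
        if kappa == 0 and (counts == 0).any():
            zero = [species[i] for i in np.where((counts == 0).all(axis=1))[0]]
            if zero:
                raise ValueError(
                    f"species with all-zero counts and kappa=0: {zero}"
                )
        r = counts + kappa
        per_rep = (np.log(r / r[ref]) - (log_c - log_c[ref])[:, None]) / n_cycles
        alpha_hat = per_rep.mean(axis=1)
        n_rep = counts.shape[1]
        se = per_rep.std(axis=1, ddof=1) / math.sqrt(n_rep) if n_rep > 1 else np.zeros(len(species))
        lo, hi = alpha_hat - zcrit * se, alpha_hat + zcrit * se
    elif method == "bayes":
        alpha_hat, se = _map_laplace_alpha(counts, log_c, ref, n_cycles, prior_sd)
        lo, hi = alpha_hat - zcrit * se, alpha_hat + zcrit * se
    else:
        raise ValueError(f"unknown method {method!r}")

    alpha_hat[ref] = lo[ref] = hi[ref] = 0.0
    return [
        EfficiencyEstimate(
            species=sp, marker_name=marker, taq=taq,
            alpha_hat=float(alpha_hat[i]), lo=float(lo[i]), hi=float(hi[i]),
            reference_species=reference_species,
        )
        for i, sp in enumerate(species)
    ]


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def _map_laplace_alpha(counts, log_c, ref, n_cycles, prior_sd):
    """Multinomial MAP for alpha (non-reference) + Laplace standard errors."""
    from scipy.optimize import minimize

    S = counts.shape[0]
    y = counts.sum(axis=1).astype(float)  # replicate likelihood factorizes
    total = y.sum()
    free = [i for i in range(S) if i != ref]

    def unpack(theta):
        alpha = np.zeros(S)
        alpha[free] = theta
        return alpha

    def neg_log_post(theta):
        alpha = unpack(theta)
        z = log_c + n_cycles * alpha
        z -= z.max()
        log_pi = z - math.log(np.exp(z).sum())
        return -(y @ log_pi) + 0.5 * float(np.sum((theta / prior_sd) ** 2))

    def grad(theta):
        alpha = unpack(theta)
        pi = softmax(log_c + n_cycles * alpha)
        g = -n_cycles * (y - total * pi)
        return g[free] + theta / prior_sd**2

    x0 = np.zeros(S - 1)
    res = minimize(neg_log_post, x0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10})
    alpha = unpack(res.x)
    pi = softmax(log_c + n_cycles * alpha)
    h = n_cycles**2 * total * (np.diag(pi) - np.outer(pi, pi))
    h = h[np.ix_(free, free)] + np.eye(S - 1) / prior_sd**2
    cov = np.linalg.inv(h)
    se = np.zeros(S)
    se[free] = np.sqrt(np.diag(cov))
    return alpha, se


def estimate_efficiencies_by_group(
    mock: MockCommunity,
    reads: ReadTable,
    n_cycles: int = DEFAULT_N_CYCLES,
    reference_species: str | None = None,
    method: str = "point",
    keys=("marker", "taq"),
    **kwargs,
) -> list[EfficiencyEstimate]:
    """Run :func:`estimate_efficiencies` per marker-Taq condition."""
    out: list[EfficiencyEstimate] = []
    for _, sub in reads.groupby_condition(keys):
        out.extend(
            estimate_efficiencies(
                mock, sub, n_cycles=n_cycles,
                reference_species=reference_species, method=method, **kwargs,
            )
        )
    return out


def calibrate_sample(
    counts: Sequence[float],
    species: Sequence[str],
    efficiencies: Sequence[EfficiencyEstimate],
    n_cycles: int = DEFAULT_N_CYCLES,
    kappa: float = DEFAULT_KAPPA,
    n_draws: int = 2000,
    seed: int | None = None,
    ci_level: float = 0.95,
    force: bool = False,
) -> CalibrationResult:
    """Invert the forward model: corrected pre-PCR composition of a sample.

    ``log w_i = log(count_i + kappa) - N alpha_i``, renormalized.
    Uncertainty is propagated by drawing alpha from normal approximations to
    the efficiency intervals.  Refuses to mix estimates across marker-Taq
    combinations unless ``force=True`` — efficiencies are only transferable
    within the combination they were measured under.
    """
    by_species = {e.species: e for e in efficiencies}
    missing = [s for s in species if s not in by_species]
    if missing:
        raise ValueError(f"no efficiency estimate for species: {missing}")
    combos = {(e.marker_name, e.taq) for e in efficiencies}
    if len(combos) > 1 and not force:
        raise ValueError(
            f"efficiency estimates span multiple marker-Taq combinations {sorted(combos)}; "
            "pass force=True only if you accept cross-protocol calibration"
        )
    counts = np.asarray(counts, dtype=float)
    alpha = np.array([by_species[s].alpha_hat for s in species])
    width = np.array([by_species[s].hi - by_species[s].lo for s in species])
    zcrit = float(-_norm_ppf((1 - ci_level) / 2))
    sd = width / (2 * zcrit)
    logw = np.log(counts + kappa) - n_cycles * alpha
    point = softmax(logw)
    rng = np.random.default_rng(seed)
    draws = rng.normal(alpha, sd, size=(n_draws, len(species)))
    comp = softmax(np.log(counts + kappa)[None, :] - n_cycles * draws, axis=1)
    lo = np.quantile(comp, (1 - ci_level) / 2, axis=0)
    hi = np.quantile(comp, 1 - (1 - ci_level) / 2, axis=0)
    return CalibrationResult(list(species), point, lo, hi)


def summarize_bias(
    estimates: Sequence[EfficiencyEstimate],
    group_by: Sequence[str] = ("marker_name", "taq"),
) -> pd.DataFrame:
    """Mean |alpha| ± SD per group, reference species excluded.

    The mean absolute efficiency is the headline bias summary: the larger
    it is, the further observed read compositions sit from the template
    composition.
    """
    df = estimates_to_frame(estimates)
    df = df[df["species"] != df["reference"]]
    rows = []
    for key, sub in df.groupby(list(group_by), sort=True):
        if sub.empty:
            continue
        key = key if isinstance(key, tuple) else (key,)
        a = sub["alpha_hat"].abs()
        rows.append(
            dict(zip(group_by, key))
            | {
                "mean_abs_alpha": a.mean(),
                "sd_abs_alpha": a.std(ddof=1) if len(a) > 1 else 0.0,
                "n_species": len(a),
            }
        )
    return pd.DataFrame(rows)


def estimates_to_frame(estimates: Sequence[EfficiencyEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [e.species for e in estimates],
            "marker_name": [e.marker_name for e in estimates],
            "taq": [e.taq for e in estimates],
            "alpha_hat": [e.alpha_hat for e in estimates],
            "lo": [e.lo for e in estimates],
            "hi": [e.hi for e in estimates],
            "reference": [e.reference_species for e in estimates],
        }
    )


def frame_to_estimates(df: pd.DataFrame) -> list[EfficiencyEstimate]:
    return [
        EfficiencyEstimate(
            species=r.species, marker_name=r.marker_name, taq=r.taq,
            alpha_hat=float(r.alpha_hat), lo=float(r.lo), hi=float(r.hi),
            reference_species=r.reference,
        )
        for r in df.itertuples()
    ]
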