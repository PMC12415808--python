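"""Template quantification and mock-community bookkeeping.

Converts droplet digital PCR (ddPCR) droplet summaries into template
concentrations via Poisson occupancy statistics, converts template
copies/ng into a mtDNA:gDNA mass fraction, and builds the expected species
proportions of a mock community under either of two concentration bases:

* ``gDNA`` — total genomic DNA mass (fluorometric quantification), or
* ``template`` — copies of the amplifiable locus itself (ddPCR).

The two bases differ whenever the mitochondrial fraction of total DNA
varies across species extracts, which is exactly the hidden observation
bias the calibration module measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AVOGADRO",
    "BP_GRAMS_PER_MOL",
    "DEFAULT_DROPLET_VOLUME_UL",
    "DEFAULT_MITO_LENGTH_BP",
    "DdpcrWell",
    "SpeciesQuant",
    "MockCommunity",
    "ConcentrationEstimate",
    "SaturationError",
    "call_positive_droplets",
    "ddpcr_concentration",
    "copies_to_mass_fraction",
    "mass_fraction_from_copies_per_ng",
    "expected_proportions",
    "build_mock_community",
    "mass_fraction_table",
    "read_wells_tsv",
    "read_species_quant_tsv",
]

AVOGADRO = 6.02214076e23
#: Mean molar mass of a double-stranded base pair, g/mol.
BP_GRAMS_PER_MOL = 660.0
#: Nominal droplet volume of a Bio-Rad QX200-class instrument, µL.
DEFAULT_DROPLET_VOLUME_UL = 8.5e-4
DEFAULT_MITO_LENGTH_BP = 16_500


class SaturationError(ValueError):
    """All droplets positive: concentration not estimable."""


@dataclass(frozen=True)
class DdpcrWell:
    sample_id: str
    marker_name: str
    n_total: int
    n_positive: int
    droplet_volume_uL: float = DEFAULT_DROPLET_VOLUME_UL
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if self.droplet_volume_uL <= 0:
            raise ValueError("droplet_volume_uL must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Point estimate and CI for a template concentration, copies/µL."""

    estimate: float
    lo: float
    hi: float
    lam: float  # mean copies per droplet

@dataclass(frozen=True)
class SpeciesQuant:
    """Per-extract quantification: total gDNA and locus template copies."""

    species: str
    taxon_class: str
    gdna_ng_per_uL: float
    template_copies_per_uL: float
    mito_length_bp: int = DEFAULT_MITO_LENGTH_BP

    def __post_init__(self) -> None:
        if self.gdna_ng_per_uL < 0 or self.template_copies_per_uL < 0:
            raise ValueError("concentrations must be non-negative")
        if self.mito_length_bp <= 0:
            raise ValueError("mito_length_bp must be positive")


@dataclass
class MockCommunity:
    """A known mixture of species extracts with expected proportions."""

    members: list[SpeciesQuant]
    volumes_uL: np.ndarray
    basis: str  # "gDNA" | "template"
    expected_proportions: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        names = [m.species for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError("member species names must be unique")
        self.volumes_uL = np.asarray(self.volumes_uL, dtype=float)
        if self.expected_proportions is None:
            self.expected_proportions = expected_proportions(
                self.members, self.volumes_uL, self.basis
            )
        self.expected_proportions = np.asarray(self.expected_proportions, float)
        if np.any(self.expected_proportions < 0):
            raise ValueError("proportions must be non-negative")
        if abs(self.expected_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1 within 1e-12")

    @property
    def species(self) -> list[str]:
        return [m.species for m in self.members]


def call_positive_droplets(
    sample_amplitudes: Sequence[float],
    ntc_amplitudes: Sequence[float],
    margin: float = 0.0,
) -> int:
    """Count droplets above the no-template-control baseline.

    The threshold is ``max(ntc_amplitudes) + margin``; droplets strictly
    above it are called positive.
    """
    ntc = np.asarray(ntc_amplitudes, dtype=float)
    if ntc.size == 0:
        raise ValueError("no NTC amplitudes: threshold undefined")
    sample = np.asarray(sample_amplitudes, dtype=float)
    if sample.size == 0:
        raise ValueError("no sample amplitudes")
    threshold = float(ntc.max()) + margin
    return int((sample > threshold).sum())


def ddpcr_concentration(well: DdpcrWell, ci_level: float = 0.95) -> ConcentrationEstimate:
    """Poisson inversion of a droplet summary into copies/µL.

    With positive fraction p, the mean occupancy is λ = −ln(1−p) and the
    stock concentration is λ / droplet_volume × dilution.  The CI is a
    Wilson score interval on p pushed through the same transform.
    """
    if well.n_positive == well.n_total:
        raise SaturationError(
            f"well {well.sample_id}: all {well.n_total} droplets positive"
        )
    p = well.n_positive / well.n_total
    lam = -math.log1p(-p)
    scale = well.dilution_factor / well.droplet_volume_uL
    lo_p, hi_p = proportion_confint(
        well.n_positive, well.n_total, alpha=1 - ci_level, method="wilson"
    )
    hi_p = min(hi_p, 1.0 - 1e-15)
    return ConcentrationEstimate(
        estimate=lam * scale,
        lo=-math.log1p(-lo_p) * scale,
        hi=-math.log1p(-hi_p) * scale,
        lam=lam,
    )


def mass_per_copy_ng(mito_length_bp: int, bp_grams_per_mol: float = BP_GRAMS_PER_MOL) -> float:
    """Mass in ng of one double-stranded molecule of the given length."""
    if mito_length_bp <= 0:
        raise ValueError("mito_length_bp must be positive")
    return mito_length_bp * bp_grams_per_mol / AVOGADRO * 1e9


def copies_to_mass_fraction(
    copies_per_ng: float,
    mito_length_bp: int,
    bp_grams_per_mol: float = BP_GRAMS_PER_MOL,
) -> float:
    """Convert template copies per ng of total DNA into a mass fraction.

    A copies/ng rate of 0 maps to 0; otherwise inputs must be positive.
    The default molar mass (660 g/mol/bp, double-stranded) and Avogadro's
    number are module constants so the conversion is auditable.
    """
    if copies_per_ng < 0:
        raise ValueError("copies_per_ng must be non-negative")
    return copies_per_ng * mass_per_copy_ng(mito_length_bp, bp_grams_per_mol)


# Alias used by table builders.
mass_fraction_from_copies_per_ng = copies_to_mass_fraction


def expected_proportions(
    members: Sequence[SpeciesQuant],
    volumes_uL: Sequence[float],
    basis: str,
) -> np.ndarray:
    """Expected mixture proportions under a concentration basis.

    ``proportion_i = amount_i / Σ amount`` where amount is volume × gDNA
    mass concentration (basis ``gDNA``) or volume × template copy
    concentration (basis ``template``).
    """
    if len(members) < 2:
        raise ValueError("need at least two community members")
    vols = np.asarray(volumes_uL, dtype=float)
    if vols.shape != (len(members),):
        raise ValueError("one input volume per member required")
    if basis == "gDNA":
        conc = np.array([m.gdna_ng_per_uL for m in members])
    elif basis == "template":
        conc = np.array([m.template_copies_per_uL for m in members])
    else:
        raise ValueError(f"unknown basis {basis!r} (expected 'gDNA' or 'template')")
    missing = [m.species for m, c in zip(members, conc) if not np.isfinite(c)]
    if missing:
        raise ValueError(f"missing {basis} measurement for: {missing}")
    amounts = vols * conc
    total = amounts.sum()
    if total <= 0:
        raise ValueError(f"all-zero {basis} amounts: proportions undefined")
    return amounts / total


def build_mock_community(
    members: Sequence[SpeciesQuant],
    volumes_uL: Sequence[float],
    basis: str,
) -> MockCommunity:
    return MockCommunity(list(members), np.asarray(volumes_uL, float), basis)


def mass_fraction_table(
    members: Sequence[SpeciesQuant],
    volumes_uL: Sequence[float],
) -> pd.DataFrame:
    """Per-species proportions under both bases plus mtDNA mass fraction.

    Proportions are always renormalized from the per-species amounts, never
    copied from an external table.
    """
    p_g = expected_proportions(members, volumes_uL, "gDNA")
    p_t = expected_proportions(members, volumes_uL, "template")
    rows = []
    for m, pg, pt in zip(members, p_g, p_t):
        copies_per_ng = (
            m.template_copies_per_uL / m.gdna_ng_per_uL if m.gdna_ng_per_uL > 0 else float("nan")
        )
        frac = (
            copies_to_mass_fraction(copies_per_ng, m.mito_length_bp)
            if np.isfinite(copies_per_ng)
            else float("nan")
        )
        rows.append(
            {
                "species": m.species,
                "class": m.taxon_class,
                "proportion_gDNA": pg,
                "proportion_mtDNA": pt,
                "mtdna_mass_fraction": frac,
            }
        )
    return pd.DataFrame(rows)


def read_wells_tsv(path) -> list[DdpcrWell]:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "marker", "n_total", "n_positive"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"wells TSV missing columns: {sorted(missing)}")
    wells = []
    for r in df.itertuples():
        wells.append(
            DdpcrWell(
                sample_id=str(r.sample_id),
                marker_name=str(r.marker),
                n_total=int(r.n_total),
                n_positive=int(r.n_positive),
                droplet_volume_uL=float(getattr(r, "droplet_volume_uL", DEFAULT_DROPLET_VOLUME_UL)),
                dilution_factor=float(getattr(r, "dilution", 1.0)),
            )
        )
    return wells


def read_species_quant_tsv(path) -> list[SpeciesQuant]:
    df = pd.read_csv(path, sep="\t")
    need = {"species", "class", "gdna_ng_per_uL", "copies_per_uL"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"species quant TSV missing columns: {sorted(missing)}")
    has_len = "mito_length_bp" in df.columns
    return [
        SpeciesQuant(
            species=str(row["species"]),
            taxon_class=str(row["class"]),
            gdna_ng_per_uL=float(row["gdna_ng_per_uL"]),
            template_copies_per_uL=float(row["copies_per_uL"]),
            mito_length_bp=int(row["mito_length_bp"]) if has_len else DEFAULT_MITO_LENGTH_BP,
        )
        for _, row in df.iterrows()
    ]
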