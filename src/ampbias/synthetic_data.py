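"""Synthetic mock-community experiments.

Generates fully synthetic inputs — communities, template sequences, read
tables, and ddPCR droplet data — with the statistical structure the
analysis modules assume, so the whole pipeline is testable end to end
without any external sequence downloads.

What is emulated: a 26-member community of two taxonomic groups ("fish",
~91% of total gDNA, GC-rich amplicons; "cetacean", ~9%, GC-poor and with
shorter 16S inserts), species-specific mitochondrial-to-total-DNA mass
fractions (log-normal across species), per-marker mismatch structure (two
perfect-match markers, one fish-targeted marker whose non-target group has
forward-primer mismatches, one marker whose mismatches are shared by every
species), per-cycle efficiencies generated linearly from mismatch/GC/length
relative to a reference species, multinomial or Dirichlet-multinomial read
sampling across technical triplicates, and Poisson droplet partitioning.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import ReadTable, forward_read_proportions, simulate_read_counts
from .insilico_pcr import IUPAC_EXPANSION, PrimerPair, reverse_complement
from .quantification import (
    DdpcrWell,
    MockCommunity,
    SpeciesQuant,
    build_mock_community,
    mass_per_copy_ng,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_community",
    "generate_templates",
    "synthesize_template",
    "generate_experiment",
    "generate_ddpcr",
    "default_panel_roles",
]

#: Default per-cycle attribution coefficients per Taq: (mismatch slope,
#: GC slope).  Mismatch slopes span the plausible per-cycle range for
#: polymerases of varying mismatch tolerance; only one polymerase has a
#: (small, positive) GC effect.  Fragment length has a small shared slope.
DEFAULT_TRUE_BETAS: Mapping[str, tuple[float, float]] = {
    "NPHF": (-0.0106, 8.49e-4),
    "IPSF": (-0.0179, 0.0),
    "PGTF": (-0.0153, 0.0),
    "QMMM": (-0.0264, 0.0),
}
DEFAULT_BETA_LEN = 5.45e-4


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic mock community.

    Defaults mirror the emulated experiment: 12 fish + 14 cetaceans mixed
    at a 91:9 gDNA mass split with equal gDNA within each group; fish
    amplicons at 45-50% GC vs. cetaceans at 35-40%; cetacean 16S inserts
    ~20 bp shorter; mtDNA mass fractions log-normal with median 2e-5
    (consistent with mtDNA being at most a few 1e-5 of total extract
    mass); triplicate reactions at 50k reads.
    """

    n_fish: int = 12
    n_cetacean: int = 14
    group_gdna_split: float = 0.91  # fish share of total gDNA mass
    total_gdna_ng: float = 100.0
    gc_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"fish": (0.45, 0.50), "cetacean": (0.35, 0.40)}
    )
    insert_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "MarVer1": 200, "MiFishU": 170, "MarVer3": 245, "Ceph16S": 230,
        }
    )
    cetacean_16s_offset: int = -20  # bp, applied to 16S markers
    mtdna_fraction_median: float = 2e-5
    mtdna_fraction_sigma_log: float = 1.0
    mito_length_bp: int = 16_500
    true_betas: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETAS)
    )
    beta_len: float = DEFAULT_BETA_LEN
    alpha_sigma: float = 0.005
    overdispersion: float = 0.0
    depth: int = 50_000
    n_replicates: int = 3
    n_cycles: int = 35
    reference_species: str = "fish_01"
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_fish < 1 or self.n_cetacean < 1:
            raise ValueError("need at least one species per group")
        if not 0 < self.group_gdna_split < 1:
            raise ValueError("group_gdna_split must be in (0,1)")

    @property
    def species(self) -> list[str]:
        return [f"fish_{i + 1:02d}" for i in range(self.n_fish)] + [
            f"cetacean_{i + 1:02d}" for i in range(self.n_cetacean)
        ]

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: ("fish" if s.startswith("fish") else "cetacean") for s in self.species
        }


@dataclass
class SyntheticTruth:
    """Everything the generator knows: the ledger for recovery tests."""

    config: SimulationConfig
    community: pd.DataFrame  # species, group, gdna_ng, mtdna_fraction, template_copies
    profiles: pd.DataFrame | None = None  # species, marker, mm_fwd, mm_rev, gc, length_bp
    alphas: pd.DataFrame | None = None  # species, marker, taq, alpha_true

    @property
    def members(self) -> list[SpeciesQuant]:
        return [
            SpeciesQuant(
                species=r.species,
                taxon_class=r.group,
                gdna_ng_per_uL=r.gdna_ng,
                template_copies_per_uL=r.template_copies,
                mito_length_bp=self.config.mito_length_bp,
            )
            for r in self.community.itertuples()
        ]

    def mock(self, basis: str) -> MockCommunity:
        vols = np.ones(len(self.community))
        return build_mock_community(self.members, vols, basis)


# ---------------------------------------------------------------------------
# community

def generate_community(config: SimulationConfig) -> tuple[MockCommunity, SyntheticTruth]:
    """Draw a mock community: equal gDNA within groups, split across groups.

    Template copy concentrations follow from each species' drawn mtDNA mass
    fraction: copies = gDNA mass x fraction / mass-per-mitogenome-copy.
    Deterministic under (config, seed); the returned community uses the
    gDNA basis (rebuild under the template basis with ``truth.mock``).
    """
    rng = np.random.default_rng(config.seed)
    species = config.species
    groups = config.groups
    gdna = np.array(
        [
            config.total_gdna_ng * config.group_gdna_split / config.n_fish
            if groups[s] == "fish"
            else config.total_gdna_ng * (1 - config.group_gdna_split) / config.n_cetacean
            for s in species
        ]
    )
    frac = rng.lognormal(
        mean=np.log(config.mtdna_fraction_median),
        sigma=config.mtdna_fraction_sigma_log,
        size=len(species),
    )
    copies = gdna * frac / mass_per_copy_ng(config.mito_length_bp)
    community = pd.DataFrame(
        {
            "species": species,
            "group": [groups[s] for s in species],
            "gdna_ng": gdna,
            "mtdna_fraction": frac,
            "template_copies": copies,
        }
    )
    truth = SyntheticTruth(config=config, community=community)
    return truth.mock("gDNA"), truth


# ---------------------------------------------------------------------------
# mismatch / GC / length profiles and template sequences

def default_panel_roles(panel: Sequence[PrimerPair]) -> dict[str, str]:
    """Assign each marker a mismatch-structure role.

    ``perfect``: no mismatches to any species; ``fish_targeted``: the
    non-target group carries forward-primer mismatches; ``shared``: every
    species shares the same mismatch load (which, being common to all,
    cancels out of the composition).
    """
    roles = {}
    for i, pair in enumerate(panel):
        if pair.marker_name in ("MarVer1", "MarVer3"):
            roles[pair.marker_name] = "perfect"
        elif pair.marker_name == "MiFishU":
            roles[pair.marker_name] = "fish_targeted"
        elif pair.marker_name == "Ceph16S":
            roles[pair.marker_name] = "shared"
        else:
            roles[pair.marker_name] = ["perfect", "fish_targeted", "shared"][i % 3]
    return roles


def _draw_profiles(config: SimulationConfig, panel, rng) -> pd.DataFrame:
    roles = default_panel_roles(panel)
    rows = []
    for s in config.species:
        group = config.groups[s]
        lo, hi = config.gc_ranges[group]
        for pair in panel:
            marker = pair.marker_name
            role = roles[marker]
            if role == "perfect":
                mm_f, mm_r = 0, 0
            elif role == "fish_targeted":
                if group == "cetacean":
                    mm_f, mm_r = 4, 0
                else:
                    mm_f = int(rng.choice([0, 0, 0, 0, 2, 4], p=[0.6, 0.1, 0.1, 0.05, 0.1, 0.05]))
                    mm_r = int(rng.random() < 0.1)
            else:  # shared
                mm_f, mm_r = 1, 3
                if group == "fish" and rng.random() < 0.15:
                    mm_f += 1
            length = config.insert_lengths[marker]
            if pair.gene == "16S" and group == "cetacean":
                length += config.cetacean_16s_offset
            gc = float(rng.uniform(lo, hi))
            rows.append(
                {
                    "species": s,
                    "marker": marker,
                    "mm_fwd": mm_f,
                    "mm_rev": mm_r,
                    "mm_total": mm_f + mm_r,
                    "gc": gc,
                    "length_bp": int(length),
                }
            )
    return pd.DataFrame(rows)


def _nondegenerate_positions(primer: str) -> list[int]:
    return [i for i, c in enumerate(primer) if len(IUPAC_EXPANSION[c]) == 1]


def _concretize_primer(primer: str, n_mismatches: int, rng) -> str:
    """A concrete binding-site sequence with exactly n mismatches.

    Mismatch positions are drawn uniformly among non-degenerate primer
    positions (so planted counts are unambiguous); every other position is
    a random member of its expansion set.
    """
    positions = _nondegenerate_positions(primer)
    if n_mismatches > len(positions):
        raise ValueError(
            f"cannot plant {n_mismatches} mismatches in primer with "
            f"{len(positions)} non-degenerate positions"
        )
    mm_pos = set(rng.choice(positions, size=n_mismatches, replace=False).tolist())
    out = []
    for i, code in enumerate(primer):
        exp = IUPAC_EXPANSION[code]
        if i in mm_pos:
            out.append(str(rng.choice(sorted(set("ACGT") - exp))))
        else:
            out.append(str(rng.choice(sorted(exp))))
    return "".join(out)


def _random_insert(length: int, gc: float, rng) -> str:
    n_gc = int(round(gc * length))
    if not 0 <= n_gc <= length:
        raise ValueError(f"requested GC {gc} unreachable at length {length}")
    bases = [str(rng.choice(["G", "C"])) for _ in range(n_gc)] + [
        str(rng.choice(["A", "T"])) for _ in range(length - n_gc)
    ]
    rng.shuffle(bases)
    return "".join(bases)


def synthesize_template(
    pair: PrimerPair,
    mm_fwd: int,
    mm_rev: int,
    gc: float,
    length_bp: int,
    rng,
    flank: int = 25,
    fwd_insertion_at: int | None = None,
    max_tries: int = 100,
) -> str:
    """One plus-strand template with planted binding sites and insert.

    ``fwd_insertion_at`` inserts one random base at that offset inside the
    forward binding region — the case of a template whose binding region
    carries an insertion, shifting the best ungapped placement.

    The draw is rejection-sampled (still a pure function of ``rng``) until
    the binding-site search recovers exactly the planted mismatch and gap
    counts at the planted coordinates, so profile round trips are exact:
    random flanks or a lucky gapped alignment occasionally score below the
    planted site, and such draws are discarded.
    """
    from .insilico_pcr import find_binding_site

    if fwd_insertion_at is not None and not 0 < fwd_insertion_at < len(pair.forward):
        raise ValueError("insertion offset must be interior to the binding site")
    _random_insert(length_bp, gc, rng=np.random.default_rng(0))  # validate GC early
    want_gaps = 0 if fwd_insertion_at is None else 1
    for _ in range(max_tries):
        fwd_site = _concretize_primer(pair.forward, mm_fwd, rng)
        rev_site = reverse_complement(_concretize_primer(pair.reverse, mm_rev, rng))
        if fwd_insertion_at is not None:
            fwd_site = (
                fwd_site[:fwd_insertion_at]
                + str(rng.choice(list("ACGT")))
                + fwd_site[fwd_insertion_at:]
            )
        insert = _random_insert(length_bp, gc, rng)
        flank5 = "".join(str(rng.choice(list("ACGT"))) for _ in range(flank))
        flank3 = "".join(str(rng.choice(list("ACGT"))) for _ in range(flank))
        tpl = flank5 + fwd_site + insert + rev_site + flank3
        fwd = find_binding_site(tpl, pair.forward, "forward")
        rev = find_binding_site(tpl, pair.reverse, "reverse")
        if (
            fwd is not None
            and rev is not None
            and (fwd.mismatches, fwd.gaps) == (mm_fwd, want_gaps)
            and (rev.mismatches, rev.gaps) == (mm_rev, 0)
            and fwd.end == flank + len(fwd_site)
            and rev.start == flank + len(fwd_site) + length_bp
        ):
            return tpl
    raise RuntimeError(
        f"could not realize profile (mm_fwd={mm_fwd}, mm_rev={mm_rev}, "
        f"gc={gc}, len={length_bp}) for {pair.marker_name} in {max_tries} tries"
    )


def generate_templates(
    truth: SyntheticTruth,
    panel: Sequence[PrimerPair],
    seed: int,
    flank: int = 25,
) -> dict[str, str]:
    """Template sequences realizing the truth's per-species profiles.

    One record per species x marker, identifiers ``species|marker``.
    Running the in-silico PCR on the output recovers each planted profile
    exactly (mismatch counts, GC, insert length).
    """
    rng = np.random.default_rng(seed)
    if truth.profiles is None:
        truth.profiles = _draw_profiles(
            truth.config, panel, _stream(truth.config.seed, 0)
        )
    pairs = {p.marker_name: p for p in panel}
    out: dict[str, str] = {}
    for r in truth.profiles.itertuples():
        pair = pairs[r.marker]
        out[f"{r.species}|{r.marker}"] = synthesize_template(
            pair, r.mm_fwd, r.mm_rev, r.gc, r.length_bp, rng, flank=flank
        )
    return out


def _stream(seed: int, key: int) -> np.random.Generator:
    """An independent, purpose-keyed RNG stream derived from one seed.

    Keying (rather than sharing one stream) keeps each artifact — profiles,
    efficiencies, read counts — identical no matter which generators were
    called before it.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# read-count experiments

def _relative(profile: pd.DataFrame, reference: str) -> pd.DataFrame:
    ref = profile[profile["species"] == reference].set_index("marker")
    rel = profile.copy()
    rel["mm_rel"] = [
        r.mm_total - ref.loc[r.marker, "mm_total"] for r in profile.itertuples()
    ]
    rel["gc_rel"] = [r.gc - ref.loc[r.marker, "gc"] for r in profile.itertuples()]
    rel["len_rel"] = [
        r.length_bp - ref.loc[r.marker, "length_bp"] for r in profile.itertuples()
    ]
    return rel


def generate_experiment(
    truth: SyntheticTruth,
    panel: Sequence[PrimerPair],
    taqs: Sequence[str] = ("NPHF", "IPSF", "PGTF", "QMMM"),
    treatments: Sequence[tuple[bool, str]] = ((False, "normal"),),
    seed: int | None = None,
    bsa_shifts: Mapping[str, float] | None = None,
    td_shifts: Mapping[str, float] | None = None,
    markers: Sequence[str] | None = None,
) -> tuple[ReadTable, SyntheticTruth]:
    """Simulate replicate read tables for marker x Taq x treatment cells.

    Per-cycle efficiencies are generated from the truth's profiles via the
    configured attribution coefficients plus N(0, alpha_sigma) noise, then
    pushed through the forward model at the community's template copies;
    optional BSA / touchdown log-ratio shifts perturb the logits directly.
    Returns the read table and the truth updated with the alpha ledger.
    """
    config = truth.config
    missing = [t for t in taqs if t not in config.true_betas]
    if missing:
        raise ValueError(f"no true betas for Taq levels: {missing}")
    base_seed = config.seed if seed is None else seed
    rng = _stream(base_seed, 1)  # alpha noise + read sampling
    if truth.profiles is None:
        truth.profiles = _draw_profiles(config, panel, _stream(config.seed, 0))
    rel = _relative(truth.profiles, config.reference_species)
    species = config.species
    log_c = np.log(truth.community.set_index("species").loc[species, "template_copies"].values)

    use_markers = list(markers) if markers else [p.marker_name for p in panel]
    alpha_rows = []
    counts = {}
    meta_rows = {}
    for marker in use_markers:
        sub = rel[rel["marker"] == marker].set_index("species").loc[species]
        for taq in taqs:
            b1, b2 = config.true_betas[taq]
            alpha = (
                b1 * sub["mm_rel"].values
                + b2 * sub["gc_rel"].values
                + config.beta_len * sub["len_rel"].values
                + rng.normal(0.0, config.alpha_sigma, size=len(species))
            )
            alpha[species.index(config.reference_species)] = 0.0
            for s, a in zip(species, alpha):
                alpha_rows.append(
                    {"species": s, "marker": marker, "taq": taq, "alpha_true": float(a)}
                )
            for bsa, cycling in treatments:
                shift = np.zeros(len(species))
                if bsa and bsa_shifts:
                    shift += np.array([bsa_shifts.get(s, 0.0) for s in species])
                if cycling != "normal" and td_shifts:
                    shift += np.array([td_shifts.get(s, 0.0) for s in species])
                pi = forward_read_proportions(
                    log_template=log_c + shift, alpha=alpha, n_cycles=config.n_cycles
                )
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{marker}.{taq}.{'BSA' if bsa else 'noBSA'}.{cycling}.r{rep}"
                    counts[sid] = simulate_read_counts(
                        pi, config.depth, config.overdispersion, rng
                    )
                    meta_rows[sid] = {
                        "marker": marker,
                        "taq": taq,
                        "bsa": bool(bsa),
                        "cycling": cycling,
                        "replicate": rep,
                    }
    reads = ReadTable(
        pd.DataFrame(counts, index=species),
        pd.DataFrame.from_dict(meta_rows, orient="index"),
    )
    truth.alphas = pd.DataFrame(alpha_rows)
    return reads, truth


# ---------------------------------------------------------------------------
# ddPCR

def generate_ddpcr(
    concentration: float,
    n_droplets: int = 20_000,
    droplet_volume_uL: float = 8.5e-4,
    seed: int | None = None,
    sample_id: str = "synthetic",
    marker_name: str = "MarVer1",
    with_amplitudes: bool = False,
):
    """Partition a template at the given copies/µL into droplets.

    Per-droplet occupancy is Poisson(concentration x droplet volume); a
    droplet is positive when it holds at least one copy.  With
    ``with_amplitudes=True`` also returns two-Gaussian fluorescence
    amplitudes (a stated stand-in for real droplet-reader output) for
    threshold-calling tests.
    """
    if concentration < 0 or n_droplets < 1 or droplet_volume_uL <= 0:
        raise ValueError("inputs must be positive (concentration may be zero)")
    rng = np.random.default_rng(seed)
    lam = concentration * droplet_volume_uL
    occupancy = rng.poisson(lam, size=n_droplets)
    positive = occupancy > 0
    well = DdpcrWell(
        sample_id=sample_id,
        marker_name=marker_name,
        n_total=n_droplets,
        n_positive=int(positive.sum()),
        droplet_volume_uL=droplet_volume_uL,
    )
    if not with_amplitudes:
        return well
    amplitudes = np.where(
        positive,
        rng.normal(8000.0, 300.0, size=n_droplets),
        rng.normal(1000.0, 100.0, size=n_droplets),
    )
    return well, amplitudes, positive
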