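"""IUPAC-aware virtual PCR.

Locates primer binding sites on template sequences, counts primer-template
mismatches under IUPAC degeneracy rules, and extracts the amplified insert
(the amplicon *without* the primer binding regions) together with its GC
content and length.  These per species x marker profiles are the raw
material for explaining amplification-efficiency differences downstream.

Matching rules
--------------
A degenerate primer base matches a template base when the template base lies
in the primer base's expansion set (an ``A`` in the template is a perfect
match to an ``R`` primer base, since R = A/G).  An ambiguous ``N`` in the
*template* matches nothing except a primer ``N`` — templates are expected to
be concrete sequences, so an N there is treated conservatively.

Site search minimizes ``(mismatches, gaps)`` lexicographically: an ungapped
(Hamming) placement is preferred, and a gapped placement is reported only
when spending up to ``max_gaps`` unit-cost indels strictly reduces the
mismatch count — the situation that arises when the binding region carries
an insertion and the best ungapped placement is shifted.  Coordinates are
0-based half-open on the plus strand of the searched sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_EXPANSION",
    "AlphabetError",
    "PrimerPair",
    "BindingSite",
    "AmpliconProfile",
    "iupac_match",
    "expansion_set",
    "degeneracy",
    "reverse_complement",
    "find_binding_site",
    "virtual_pcr",
    "profile_panel",
    "load_primer_panel",
    "read_primer_tsv",
    "read_templates_fasta",
]

#: Expansion sets of the 15 IUPAC nucleotide codes.
IUPAC_EXPANSION: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_TEMPLATE_ALPHABET = frozenset("ACGTN")

#: Default ceiling on per-primer mismatches before a template is declared
#: non-amplifiable; comfortably above the worst case seen in practice (6).
DEFAULT_MAX_MISMATCHES = 8


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the permitted alphabet."""


def _validate_iupac(seq: str, what: str) -> None:
    if not seq:
        raise AlphabetError(f"{what} is empty")
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_EXPANSION:
            raise AlphabetError(
                f"invalid IUPAC symbol {ch!r} at position {pos} in {what}"
            )


def _validate_template(seq: str, what: str = "template") -> None:
    if not seq:
        raise AlphabetError(f"{what} is empty")
    for pos, ch in enumerate(seq):
        if ch not in _TEMPLATE_ALPHABET:
            raise AlphabetError(
                f"invalid template symbol {ch!r} at position {pos} in {what}"
            )


def expansion_set(code: str) -> frozenset:
    """Return the set of concrete bases an IUPAC code stands for."""
    try:
        return IUPAC_EXPANSION[code]
    except KeyError:
        raise AlphabetError(f"invalid IUPAC symbol {code!r}") from None


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True iff ``template_base`` lies in the expansion set of ``primer_base``.

    ``template_base`` must be unambiguous (A/C/G/T).  A primer ``N`` matches
    every template base.
    """
    exp = expansion_set(primer_base)
    if template_base not in IUPAC_EXPANSION or len(IUPAC_EXPANSION[template_base]) != 1:
        raise AlphabetError(
            f"template base {template_base!r} is not an unambiguous nucleotide"
        )
    return template_base in exp


def _match(primer_base: str, template_base: str) -> bool:
    # Scanning-time rule: template N matches only primer N.
    if template_base == "N":
        return primer_base == "N"
    return template_base in IUPAC_EXPANSION[primer_base]


def degeneracy(primer: str) -> int:
    """Number of concrete sequences a degenerate primer expands to."""
    _validate_iupac(primer, "primer")
    d = 1
    for ch in primer:
        d *= len(IUPAC_EXPANSION[ch])
    return d


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, S<->S, ...)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """One marker's primer pair, both primers written 5'->3' as synthesized."""

    marker_name: str
    gene: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        _validate_iupac(self.forward, f"forward primer of {self.marker_name}")
        _validate_iupac(self.reverse, f"reverse primer of {self.marker_name}")

    @property
    def degeneracy_forward(self) -> int:
        return degeneracy(self.forward)

    @property
    def degeneracy_reverse(self) -> int:
        return degeneracy(self.reverse)


@dataclass(frozen=True)
class BindingSite:
    """A primer placement on a template, plus-strand half-open coordinates."""

    template_id: str
    primer_role: str  # "forward" | "reverse"
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    gaps: int
    offset: int  # shift of the chosen placement vs. the best ungapped one

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("binding site end must exceed start")
        if self.mismatches < 0 or self.gaps < 0:
            raise ValueError("mismatches and gaps must be non-negative")


@dataclass
class AmpliconProfile:
    """Mismatch / GC / length profile of one species x marker amplicon."""

    species: str
    marker_name: str
    mm_fwd: int = 0
    mm_rev: int = 0
    gc: float = float("nan")
    length_bp: int = 0
    amplifiable: bool = False
    reason: str = ""  # machine-readable reason when not amplifiable
    fwd_site: BindingSite | None = field(default=None, repr=False)
    rev_site: BindingSite | None = field(default=None, repr=False)

    @property
    def mm_total(self) -> int:
        return self.mm_fwd + self.mm_rev


def _best_placements(template: str, primer: str, max_gaps: int):
    """Best placement of ``primer`` for each gap budget 0..max_gaps.

    Semi-global alignment (free template ends) minimizing mismatches with at
    most g unit-cost indels.  Gaps must be internal to the binding site: the
    first and last primer bases always pair with template bases, so a
    terminal mismatch can never be reinterpreted as a cheaper boundary gap.
    Returns ``res[g] = (mismatches, start, end)``, ties broken by leftmost
    start then smallest end.
    """
    n, m = len(template), len(primer)
    if n < m - max_gaps:
        big = 10**9
        return [(big, 0, min(n, 1) or 1) for _ in range(max_gaps + 1)]
    INF = (10**9, 10**9)
    G = max_gaps
    # prev[g][j]: best (mismatches, start) aligning primer[:i] ending at
    # template offset j with <= g gaps.
    prev = [[(0, j) for j in range(n + 1)] for _ in range(G + 1)]
    for i in range(1, m + 1):
        pb = primer[i - 1]
        match_row = [False] + [_match(pb, template[j - 1]) for j in range(1, n + 1)]
        # internal gaps only: no deletion of the terminal primer bases, no
        # template-base skip after the final primer base
        allow_del = 1 < i < m
        allow_ins = i < m
        cur = [[INF] * (n + 1) for _ in range(G + 1)]
        for g in range(G + 1):
            prow = prev[g]
            crow = cur[g]
            pgap = prev[g - 1] if g else None
            cgap = cur[g - 1] if g else None
            for j in range(n + 1):
                best = INF
                if j:
                    mm, st = prow[j - 1]
                    if not match_row[j]:
                        mm += 1
                    if (mm, st) < best:
                        best = (mm, st)
                if g:
                    if allow_del:
                        cand = pgap[j]  # primer base unmatched (gap in template)
                        if cand < best:
                            best = cand
                    if j and allow_ins:
                        cand = cgap[j - 1]  # template base skipped (gap in primer)
                        if cand < best:
                            best = cand
                crow[j] = best
        prev = cur
    out = []
    for g in range(G + 1):
        mm, st, end = min(
            (prev[g][j][0], prev[g][j][1], j) for j in range(n + 1)
        )
        out.append((mm, st, end))
    return out


def find_binding_site(
    template: str,
    primer: str,
    role: str = "forward",
    max_gaps: int = 1,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    template_id: str = "",
) -> BindingSite | None:
    """Locate the best binding site of ``primer`` on ``template``.

    For ``role="reverse"`` the primer is reverse-complemented before the
    search (it binds the minus strand) and the site is reported on minus
    strand with plus-strand coordinates.  Returns ``None`` when no placement
    achieves ``mismatches <= max_mismatches`` (a not-found result, distinct
    from an input error).
    """
    template = template.upper()
    _validate_template(template, template_id or "template")
    _validate_iupac(primer, "primer")
    if role not in ("forward", "reverse"):
        raise ValueError(f"role must be 'forward' or 'reverse', got {role!r}")
    query = reverse_complement(primer) if role == "reverse" else primer
    placements = _best_placements(template, query, max_gaps)
    # Lexicographic (mismatches, gaps): gapped wins only on strict improvement.
    mm_star = min(p[0] for p in placements)
    g_star = min(g for g, p in enumerate(placements) if p[0] == mm_star)
    mm, start, end = placements[g_star]
    if mm > max_mismatches:
        return None
    offset = start - placements[0][1] if g_star else 0
    return BindingSite(
        template_id=template_id,
        primer_role=role,
        start=start,
        end=end,
        strand="-" if role == "reverse" else "+",
        mismatches=mm,
        gaps=g_star,
        offset=offset,
    )


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases only; NaN if none."""
    unamb = [c for c in seq.upper() if c in "ACGT"]
    if not unamb:
        return float("nan")
    return sum(c in "GC" for c in unamb) / len(unamb)


def _flip_site(site: BindingSite, length: int) -> BindingSite:
    """Map a site found on the reverse complement back to input coordinates."""
    return BindingSite(
        template_id=site.template_id,
        primer_role=site.primer_role,
        start=length - site.end,
        end=length - site.start,
        strand="-" if site.strand == "+" else "+",
        mismatches=site.mismatches,
        gaps=site.gaps,
        offset=-site.offset,
    )


def virtual_pcr(
    template: str,
    pair: PrimerPair,
    max_gaps: int = 1,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    species: str = "",
    template_id: str = "",
    both_orientations: bool = True,
) -> tuple[AmpliconProfile, str]:
    """Amplify ``template`` in silico with ``pair``.

    Returns an :class:`AmpliconProfile` and the insert sequence (the region
    between the two primer binding sites, binding sites excluded).  A
    template on which either primer has no acceptable site, or on which the
    sites are inverted/overlapping, yields ``amplifiable=False`` with a
    reason code rather than an error.
    """
    template = template.upper()
    _validate_template(template, template_id or species or "template")
    tid = template_id or species

    def attempt(seq: str) -> tuple[AmpliconProfile, str]:
        prof = AmpliconProfile(species=species, marker_name=pair.marker_name)
        fwd = find_binding_site(seq, pair.forward, "forward", max_gaps,
                                max_mismatches, tid)
        if fwd is None:
            prof.reason = "forward_site_not_found"
            return prof, ""
        rev = find_binding_site(seq, pair.reverse, "reverse", max_gaps,
                                max_mismatches, tid)
        if rev is None:
            prof.reason = "reverse_site_not_found"
            return prof, ""
        if rev.start < fwd.end:
            prof.mm_fwd, prof.mm_rev = fwd.mismatches, rev.mismatches
            prof.fwd_site, prof.rev_site = fwd, rev
            prof.reason = "sites_overlapping_or_inverted"
            return prof, ""
        insert = seq[fwd.end:rev.start]
        prof.mm_fwd, prof.mm_rev = fwd.mismatches, rev.mismatches
        prof.gc = gc_fraction(insert)
        prof.length_bp = len(insert)
        prof.amplifiable = len(insert) > 0
        prof.reason = "" if prof.amplifiable else "empty_insert"
        prof.fwd_site, prof.rev_site = fwd, rev
        return prof, insert

    prof, insert = attempt(template)
    if not both_orientations:
        return prof, insert
    # The template's orientation is unknown in general: score both strands
    # and keep the better placement (fewest total mismatches, plus on ties).
    rc = reverse_complement(template)
    prof_rc, insert_rc = attempt(rc)
    if prof_rc.amplifiable and (
        not prof.amplifiable or prof_rc.mm_total < prof.mm_total
    ):
        n = len(template)
        prof_rc.fwd_site = _flip_site(prof_rc.fwd_site, n)
        prof_rc.rev_site = _flip_site(prof_rc.rev_site, n)
        return prof_rc, insert_rc
    return prof, insert


def profile_panel(
    templates: Mapping[str, str] | Iterable[tuple[str, str]],
    panel: Sequence[PrimerPair],
    max_gaps: int = 1,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> pd.DataFrame:
    """Profile every template against every primer pair.

    Row order is deterministic: template order x panel order.  Template
    identifiers must be unique.
    """
    if isinstance(templates, Mapping):
        items = list(templates.items())
    else:
        items = list(templates)
    if not items:
        raise ValueError("no templates provided")
    if not panel:
        raise ValueError("empty primer panel")
    ids = [t[0] for t in items]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate template identifiers: {dup}")
    rows = []
    for tid, seq in items:
        for pair in panel:
            prof, _ = virtual_pcr(
                seq, pair, max_gaps=max_gaps, max_mismatches=max_mismatches,
                species=tid, template_id=tid,
            )
            rows.append(
                {
                    "species": tid,
                    "marker": pair.marker_name,
                    "mm_fwd": prof.mm_fwd,
                    "mm_rev": prof.mm_rev,
                    "mm_total": prof.mm_total,
                    "gc": prof.gc,
                    "length_bp": prof.length_bp,
                    "amplifiable": prof.amplifiable,
                    "fwd_start": prof.fwd_site.start if prof.fwd_site else -1,
                    "fwd_end": prof.fwd_site.end if prof.fwd_site else -1,
                    "rev_start": prof.rev_site.start if prof.rev_site else -1,
                    "rev_end": prof.rev_site.end if prof.rev_site else -1,
                }
            )
    return pd.DataFrame(rows)


def read_primer_tsv(path) -> list[PrimerPair]:
    """Read a 4-column primer TSV (marker, gene, forward, reverse)."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker", "gene", "forward", "reverse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer TSV missing columns: {sorted(missing)}")
    return [
        PrimerPair(r.marker, r.gene, r.forward.strip().upper(), r.reverse.strip().upper())
        for r in df.itertuples()
    ]


def load_primer_panel() -> list[PrimerPair]:
    """The four packaged marine-vertebrate marker panels (12S/16S)."""
    from importlib.resources import files

    return read_primer_tsv(files("ampbias.data").joinpath("primers.tsv"))


def read_templates_fasta(path) -> dict[str, str]:
    """Read templates from FASTA into an ordered {id: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate template identifier: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out
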