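"""Extended active-site motif analysis for thioredoxin-fold sequences.

Thioredoxin-fold oxidoreductases carry a catalytic -CXXC- motif whose
N-terminal cysteine is the attacking nucleophile.  Its pKa — and hence the
protein's redox role — is tuned by residues outside the motif itself: a
(often buried) acidic residue six positions before the N-terminal cysteine
on strand beta-1, an acidic residue downstream on helix alpha-1, and a
distal hydrogen-bond/salt-bridge partner on strand beta-2 (a glutamine in
cDsbD, a lysine in E. coli thioredoxin).  This module locates -CXXC-
motifs, extracts the residues occupying these extended-site positions,
tabulates their conservation across a sequence set, and applies a
qualitative electrostatic classification of the resulting active-site type.

Offsets are relative to the N-terminal cysteine (offset 0) and 0-based
within a sequence; reports use 1-based coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "SequenceRecord",
    "ExtendedSiteConfig",
    "ExtendedSiteRecord",
    "ConservationTable",
    "Classification",
    "find_cxxc",
    "extract_extended_site",
    "tabulate_conservation",
    "classify_active_site",
]

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Residues counted as acidic at the beta-1 position.
ACIDIC = frozenset("DE")

#: Distal-partner candidates: side chains able to stabilize a buried
#: carboxylate anion by hydrogen bond (Q, N) or salt bridge (K, R, H).
PARTNER_RESIDUES = frozenset("QNKRH")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence (one-letter upper-case, standard alphabet plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be nonempty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )


@dataclass(frozen=True)
class ExtendedSiteConfig:
    """Offsets and windows of the extended-site positions.

    ``acidic_offset`` is the downstream acidic slot on helix alpha-1
    (+7 for cDsbD's Glu-468; +6 for the CcmG/ResA/StoA spacing).  The distal
    beta-2 partner cannot sit at one fixed offset across families, so it is
    found as the first candidate residue inside ``partner_window``
    (inclusive bounds, offsets from the N-terminal Cys), unless
    ``partner_offset_override`` pins an explicit alignment column.
    """

    beta1_offset: int = -6
    acidic_offset: int = 7
    partner_window: tuple[int, int] = (20, 35)
    partner_offset_override: Optional[int] = None


@dataclass(frozen=True)
class ExtendedSiteRecord:
    """Residues at the extended active-site positions of one motif.

    Slots that fall outside the sequence are None (marked missing), never
    silently truncated.  ``annotations`` carries optional user-supplied
    per-slot flags (e.g. ``{"beta1_buried": True}``) — burial comes from
    structures and is accepted only as an annotation, never computed here.
    """

    sequence_id: str
    cys_n_pos: int
    xx_residues: str
    beta1_minus6: Optional[str]
    alpha1_acidic: Optional[str]
    distal_partner: Optional[tuple[str, int]]
    config: ExtendedSiteConfig = field(default_factory=ExtendedSiteConfig)
    annotations: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class ConservationTable:
    """Residue counts and percentages for one extended-site slot.

    Percentages are over records where the slot is present; records with the
    slot missing are excluded from the denominator and counted separately.
    """

    slot: str
    counts: Mapping[str, int]
    total: int
    n_missing: int

    @property
    def percents(self) -> dict[str, float]:
        return {res: 100.0 * c / self.total for res, c in self.counts.items()}


@dataclass(frozen=True)
class Classification:
    """Active-site class label with the rule trace that produced it."""

    label: str
    rule: str
    trace: tuple[str, ...]


def find_cxxc(seq: SequenceRecord) -> list[int]:
    """All 0-based start indices of -CXXC- motifs (C, any two residues, C).

    Overlapping motifs are all reported; an empty list is a valid result.
    """
    residues = seq.residues
    return [
        i
        for i in range(len(residues) - 3)
        if residues[i] == "C" and residues[i + 3] == "C"
    ]


def _slot(residues: str, pos: int) -> Optional[str]:
    return residues[pos] if 0 <= pos < len(residues) else None


def extract_extended_site(
    seq: SequenceRecord,
    motif_index: int,
    config: ExtendedSiteConfig | None = None,
) -> ExtendedSiteRecord:
    """Extract the extended-site residues around the motif at ``motif_index``.

    ``motif_index`` must point at an N-terminal motif cysteine (as returned
    by :func:`find_cxxc`).  The distal partner is the first residue in
    :data:`PARTNER_RESIDUES` inside the configured window, or the residue at
    the explicit override offset if one is set.
    """
    config = config or ExtendedSiteConfig()
    residues = seq.residues
    if not (
        0 <= motif_index <= len(residues) - 4
        and residues[motif_index] == "C"
        and residues[motif_index + 3] == "C"
    ):
        raise ValueError(
            f"index {motif_index} is not a -CXXC- motif start in {seq.id!r}"
        )

    partner: Optional[tuple[str, int]] = None
    if config.partner_offset_override is not None:
        res = _slot(residues, motif_index + config.partner_offset_override)
        if res is not None:
            partner = (res, config.partner_offset_override)
    else:
        lo, hi = config.partner_window
        for off in range(lo, hi + 1):
            res = _slot(residues, motif_index + off)
            if res is not None and res in PARTNER_RESIDUES:
                partner = (res, off)
                break

    return ExtendedSiteRecord(
        sequence_id=seq.id,
        cys_n_pos=motif_index,
        xx_residues=residues[motif_index + 1 : motif_index + 3],
        beta1_minus6=_slot(residues, motif_index + config.beta1_offset),
        alpha1_acidic=_slot(residues, motif_index + config.acidic_offset),
        distal_partner=partner,
        config=config,
    )


def tabulate_conservation(
    records: Sequence[ExtendedSiteRecord], slot: str
) -> ConservationTable:
    """Count residues occupying ``slot`` across records.

    ``slot`` is one of ``beta1_minus6``, ``alpha1_acidic``,
    ``distal_partner`` or ``xx_residues`` (the latter counts two-residue
    strings).  Missing slots are excluded from the denominator.
    """
    valid_slots = ("beta1_minus6", "alpha1_acidic", "distal_partner", "xx_residues")
    if slot not in valid_slots:
        raise ValueError(f"unknown slot {slot!r}; expected one of {valid_slots}")
    counts: Counter[str] = Counter()
    n_missing = 0
    for rec in records:
        value = getattr(rec, slot)
        if value is None:
            n_missing += 1
            continue
        if slot == "distal_partner":
            value = value[0]
        counts[value] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"slot {slot!r} is missing from every record")
    return ConservationTable(slot=slot, counts=dict(counts), total=total, n_missing=n_missing)


def classify_active_site(record: ExtendedSiteRecord) -> Classification:
    """Qualitative electrostatic classification of an extended active site.

    The deterministic rule cascade (each firing is recorded in the trace):

    1. acidic residue on beta-1 and an amide partner (Q/N) — the hydrogen
       bond stabilizes the buried carboxylate, whose anion then raises the
       attacking cysteine's pKa (cDsbD-like stabilized acid);
    2. acidic residue on beta-1 and a basic partner (K/R) — a salt bridge
       stabilizes the acid, coupling its ionization to the cysteine's and
       producing microscopic pKa behaviour (E. coli thioredoxin-like,
       bidirectional);
    3. acidic residue on beta-1 with no partner — the unstabilized buried
       acid stays protonated and the helix dipole dominates, leaving a low
       attacking-cysteine pKa (human thioredoxin / DsbA-like);
    4. no acidic residue on beta-1 — reductant-provision-like site with a
       near-physiological cysteine pKa (CcmG/ResA/StoA-like).

    A proline or glycine between the cysteines appends a
    "thiolate-stabilizing XX" modifier: those backbones favour hydrogen
    bonding of the thiolate by the second motif cysteine's amide.
    """
    trace: list[str] = []
    beta1 = record.beta1_minus6
    partner = record.distal_partner[0] if record.distal_partner else None

    acidic = beta1 is not None and beta1 in ACIDIC
    trace.append(
        f"beta1_minus6={beta1 or 'missing'}: " + ("acidic" if acidic else "not acidic")
    )

    if acidic:
        if partner in ("Q", "N"):
            rule = "R1"
            label = "stabilized-acid / elevated attacking-Cys pKa"
            trace.append(f"distal partner {partner}: hydrogen-bond stabilizer")
        elif partner in ("K", "R"):
            rule = "R2"
            label = "coupled microscopic pKas / bidirectional"
            trace.append(f"distal partner {partner}: salt-bridge stabilizer")
        else:
            rule = "R3"
            label = "unstabilized buried acid / low attacking-Cys pKa dominated by helix dipole"
            trace.append(f"distal partner {partner or 'none'}: no anion stabilizer")
    else:
        rule = "R4"
        label = "reductant-provision-like near-physiological pKa"
        trace.append("no acidic beta1 residue: helix dipole sets the Cys pKa")

    if any(r in "PG" for r in record.xx_residues):
        label += " [thiolate-stabilizing XX]"
        trace.append(f"XX={record.xx_residues}: P/G favours thiolate H-bonding")

    return Classification(label=label, rule=rule, trace=tuple(trace))
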