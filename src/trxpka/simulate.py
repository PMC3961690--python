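"""Seeded synthetic-data generators for the whole pipeline.

Every generator is a pure function of its spec (including the seed): the
same spec yields byte-identical output.  Each returns the generated data
together with a *truth echo* — the exact ground-truth parameters used — so
downstream recovery tests never rely on hidden state.

What is emulated: per-resonance chemical-shift titrations on a pH ladder
(uniform grid 4-13 by default, the measured range for cysteine/aspartate
titrations in thioredoxin-fold domains), with Gaussian noise on the shifts
(default SD 0.05 ppm, small against the ~0.5-3 ppm amplitudes typical of
thiol titrations); triplicate densitometry readings with lognormal
(positivity-preserving) or truncated-normal spread; and sequence sets with
residues planted at the extended active-site positions under controlled
frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .activity import ReplicateSet
from .fitting import TitrationSeries
from .models import (
    CoupledSiteModel,
    OnePkaParams,
    TwoPkaParams,
    shift_one_pka,
    shift_two_pka,
    site_deprotonation_fraction,
)

__all__ = [
    "TitrationSimSpec",
    "CoupledTitrationSimSpec",
    "DensitometrySimSpec",
    "MotifSimSpec",
    "gen_titration",
    "gen_coupled_titration",
    "gen_densitometry",
    "gen_motif_sequences",
    "default_ph_grid",
]


def default_ph_grid(step: float = 0.5) -> np.ndarray:
    """Uniform pH ladder 4.0-13.0 (inclusive) with the given step."""
    n = int(round((13.0 - 4.0) / step))
    return np.linspace(4.0, 13.0, n + 1)


@dataclass(frozen=True)
class TitrationSimSpec:
    """Simulation design for simple (one- or two-pKa) titration series.

    ``truth`` fixes the pKa value(s) and, when ``amplitude_range`` is None,
    the limiting shifts.  With ``amplitude_range`` set, each resonance draws
    its own total amplitude uniformly from the range and its baseline from
    ``baseline_range``, keeping the truth pKa(s); for a two-pKa truth the
    relative step heights of the template are preserved.
    """

    truth: Union[OnePkaParams, TwoPkaParams]
    ph_grid: np.ndarray = field(default_factory=default_ph_grid)
    noise_sd: float = 0.05
    n_resonances: int = 1
    seed: int = 0
    amplitude_range: Optional[tuple[float, float]] = None
    baseline_range: tuple[float, float] = (25.0, 35.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.ph_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("ph_grid must be nonempty")
        if not np.all(np.diff(grid) >= 0):
            raise ValueError("ph_grid must be sorted")
        object.__setattr__(self, "ph_grid", grid)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_resonances < 1:
            raise ValueError("n_resonances must be >= 1")


def _resonance_params(
    spec: TitrationSimSpec, rng: np.random.Generator
) -> Union[OnePkaParams, TwoPkaParams]:
    truth = spec.truth
    if spec.amplitude_range is None:
        return truth
    amp = float(rng.uniform(*spec.amplitude_range))
    base = float(rng.uniform(*spec.baseline_range))
    if isinstance(truth, OnePkaParams):
        return OnePkaParams(base, base + amp, truth.pka)
    total = truth.delta_state2 - truth.delta_state0
    frac1 = (truth.delta_state1 - truth.delta_state0) / total if total else 0.5
    return TwoPkaParams(base, base + frac1 * amp, base + amp, truth.pka1, truth.pka2)


def gen_titration(
    spec: TitrationSimSpec,
) -> tuple[list[TitrationSeries], list[Union[OnePkaParams, TwoPkaParams]]]:
    """Generate titration series plus the per-resonance ground truth.

    Shifts are the closed-form model curve plus i.i.d. Gaussian noise of SD
    ``spec.noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    series: list[TitrationSeries] = []
    truths: list[Union[OnePkaParams, TwoPkaParams]] = []
    for k in range(spec.n_resonances):
        params = _resonance_params(spec, rng)
        if isinstance(params, OnePkaParams):
            clean = shift_one_pka(spec.ph_grid, params)
        else:
            clean = shift_two_pka(spec.ph_grid, params)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=spec.ph_grid.shape)
        series.append(
            TitrationSeries(
                residue_label="sim",
                nucleus_label=f"res{k + 1}",
                ph=spec.ph_grid.copy(),
                shift=noisy,
            )
        )
        truths.append(params)
    return series, truths


@dataclass(frozen=True)
class CoupledTitrationSimSpec:
    """Simulation design for coupled two-site titration observables.

    The noiseless observable is linear in the deprotonation fraction of each
    site: ``baseline + amplitude * (w_A * f_A(pH) + w_B * f_B(pH))`` with
    ``w_A + w_B = 1``.  The default weights (0, 1) give a pure site-B
    reporter — for a symmetric model, a double sigmoid with two equal steps.
    """

    model: CoupledSiteModel
    ph_grid: np.ndarray = field(default_factory=lambda: default_ph_grid(0.25))
    noise_sd: float = 0.05
    n_resonances: int = 1
    seed: int = 0
    weight_a: float = 0.0
    weight_b: float = 1.0
    amplitude_range: tuple[float, float] = (2.7, 2.7)
    baseline_range: tuple[float, float] = (25.0, 35.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.ph_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("ph_grid must be nonempty")
        object.__setattr__(self, "ph_grid", grid)
        if not math.isclose(self.weight_a + self.weight_b, 1.0, abs_tol=1e-12):
            raise ValueError("weight_a + weight_b must equal 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def coupled_clean_curve(
    spec: CoupledTitrationSimSpec, baseline: float, amplitude: float
) -> np.ndarray:
    """Noiseless coupled-site observable on the spec's pH grid."""
    f = np.zeros_like(spec.ph_grid)
    if spec.weight_a:
        f = f + spec.weight_a * site_deprotonation_fraction(spec.ph_grid, spec.model, "A")
    if spec.weight_b:
        f = f + spec.weight_b * site_deprotonation_fraction(spec.ph_grid, spec.model, "B")
    return baseline + amplitude * f


def gen_coupled_titration(
    spec: CoupledTitrationSimSpec,
) -> tuple[list[TitrationSeries], list[tuple[float, float]]]:
    """Generate coupled-site observables; truth echo is (baseline, amplitude)
    per resonance (the ionization model itself is in the spec)."""
    rng = np.random.default_rng(spec.seed)
    series: list[TitrationSeries] = []
    truths: list[tuple[float, float]] = []
    for k in range(spec.n_resonances):
        amp = float(rng.uniform(*spec.amplitude_range))
        base = float(rng.uniform(*spec.baseline_range))
        clean = coupled_clean_curve(spec, base, amp)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=spec.ph_grid.shape)
        series.append(
            TitrationSeries(
                residue_label="sim-coupled",
                nucleus_label=f"res{k + 1}",
                ph=spec.ph_grid.copy(),
                shift=noisy,
            )
        )
        truths.append((base, amp))
    return series, truths


@dataclass(frozen=True)
class DensitometrySimSpec:
    """Simulation design for replicate densitometry tables.

    ``true_means`` maps construct label to its true peak height (arbitrary
    units).  Readings are lognormal by default (guaranteed positive) with
    the requested coefficient of variation; a truncated-normal alternative
    is available.  Default CV 0.07 mirrors the ~4-7% spreads typical of
    triplicate gel densitometry.
    """

    true_means: Mapping[str, float]
    cv: float = 0.07
    n_replicates: int = 3
    n_datasets: int = 1
    seed: int = 0
    distribution: Literal["lognormal", "truncnorm"] = "lognormal"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if any(m <= 0 for m in self.true_means.values()):
            raise ValueError("true means must be > 0")
        if self.n_replicates < 2 or self.n_datasets < 1:
            raise ValueError("need >= 2 replicates and >= 1 dataset")


def gen_densitometry(spec: DensitometrySimSpec) -> pd.DataFrame:
    """Generate a replicate table with columns construct, dataset, reading."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for d in range(1, spec.n_datasets + 1):
        for construct, mean in spec.true_means.items():
            if spec.cv == 0:
                readings = np.full(spec.n_replicates, float(mean))
            elif spec.distribution == "lognormal":
                sigma2 = math.log1p(spec.cv**2)
                mu = math.log(mean) - sigma2 / 2.0
                readings = rng.lognormal(mu, math.sqrt(sigma2), spec.n_replicates)
            else:
                readings = np.abs(rng.normal(mean, spec.cv * mean, spec.n_replicates))
            for r in readings:
                rows.append({"construct": construct, "dataset": str(d), "reading": float(r)})
    return pd.DataFrame(rows, columns=["construct", "dataset", "reading"])


def replicate_sets_from_table(table: pd.DataFrame) -> list[ReplicateSet]:
    """Group a construct/dataset/reading table into :class:`ReplicateSet`s."""
    sets = []
    for (construct, dataset), grp in table.groupby(["construct", "dataset"], sort=True):
        sets.append(ReplicateSet(str(construct), str(dataset), tuple(grp["reading"])))
    return sets


# Background alphabet excludes C so the planted -CXXC- is the unique motif
# (spurious cysteine pairs would make planted-layout recovery ambiguous).
_BACKGROUND_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifSimSpec:
    """Simulation design for extended-site sequence sets.

    ``slot_frequencies`` maps slot name to a residue->frequency table
    (frequencies summing to 1): slots ``beta1_minus6``, ``xx`` (two-letter
    strings), ``alpha1_acidic``, ``partner``.  Slots absent from the map are
    filled from the background.  The partner is planted at a fixed offset
    (default +27, the cDsbD spacing) inside the default scan window.
    """

    n_sequences: int = 494
    length: int = 120
    motif_position: int = 40
    slot_frequencies: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "beta1_minus6": {"D": 1.0},
            "xx": {"VA": 1.0},
            "alpha1_acidic": {"E": 1.0},
            "partner": {"Q": 1.0},
        }
    )
    acidic_offset: int = 7
    partner_offset: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 4:
            raise ValueError("need >= 1 sequence of length >= 4")
        if not 0 <= self.motif_position <= self.length - 4:
            raise ValueError("motif_position out of bounds")
        for slot, freqs in self.slot_frequencies.items():
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"frequencies for slot {slot!r} sum to {total}, not 1")


def _draw(freqs: Mapping[str, float], rng: np.random.Generator) -> str:
    keys = sorted(freqs)
    probs = np.array([freqs[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def gen_motif_sequences(
    spec: MotifSimSpec,
) -> tuple[list, list[dict[str, str]]]:
    """Generate sequences with planted extended-site layouts.

    Returns ``(records, truth)`` where ``records`` are
    :class:`~trxpka.motifs.SequenceRecord`s and ``truth[i]`` lists the
    planted residue per slot for sequence ``i``.  Background positions are
    uniform over the standard alphabet minus cysteine.
    """
    from .motifs import SequenceRecord  # local import to avoid cycle

    rng = np.random.default_rng(spec.seed)
    records = []
    truths: list[dict[str, str]] = []
    bg = np.array(list(_BACKGROUND_ALPHABET))
    for k in range(spec.n_sequences):
        residues = list(rng.choice(bg, size=spec.length))
        m = spec.motif_position
        planted: dict[str, str] = {}
        xx = _draw(spec.slot_frequencies["xx"], rng) if "xx" in spec.slot_frequencies else "".join(rng.choice(bg, size=2))
        residues[m], residues[m + 1], residues[m + 2], residues[m + 3] = "C", xx[0], xx[1], "C"
        planted["xx"] = xx
        for slot, offset in (
            ("beta1_minus6", -6),
            ("alpha1_acidic", spec.acidic_offset),
            ("partner", spec.partner_offset),
        ):
            pos = m + offset
            if not 0 <= pos < spec.length:
                continue
            if slot in spec.slot_frequencies:
                res = _draw(spec.slot_frequencies[slot], rng)
                residues[pos] = res
                planted[slot] = res
            else:
                planted[slot] = residues[pos]
        # scrub partner-window positions before the planted partner so the
        # first-match scan lands on the planted residue deterministically
        for off in range(20, spec.partner_offset):
            pos = m + off
            if 0 <= pos < spec.length and residues[pos] in "QNKRH":
                residues[pos] = "L"
        truths.append(planted)
        records.append(SequenceRecord(id=f"seq{k + 1:04d}", residues="".join(residues)))
    return records, truths
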