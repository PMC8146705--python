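"""Synthetic fixtures: proteomes with planted markers, concentration-response
peak-area tables, chromatogram traces, and sausage-formulation arithmetic.

Nothing here downloads anything.  The generators emulate the *structure* of
the real study conditions — nine species panels, matrix-calibration ladders
from 0.1 to 2.5 % meat substitution, twelve replicate measurements of
unknowns, multiplicative (lognormal) peak-area noise — with a ground-truth
manifest so every downstream stage's expected output is computable.  They do
not model ionization efficiency, matrix suppression beyond a per-marker
slope, or retention-time drift.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import ProteinRecord

__all__ = [
    "SimulationDesign",
    "FormulationParams",
    "make_proteomes",
    "simulate_area_table",
    "simulate_chromatogram",
    "flour_for_substitution",
    "substitution_for_flour",
    "DEFAULT_SPECIES",
]

#: the nine-legume panel the default simulations emulate
DEFAULT_SPECIES = (
    "Alfalfa",
    "Broad bean",
    "Chickpea",
    "Lentil",
    "Lupine blue",
    "Lupine white",
    "Pea",
    "Peanut",
    "Soy",
)

# backbone alphabet weighted so tryptic peptides average ~10-14 residues
# (K+R frequency ~ 1/12); cysteine kept rare, as in real seed proteins.
_BACKBONE_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_BACKBONE_WEIGHTS = np.array(
    [
        0.075,  # A
        0.010,  # C
        0.055,  # D
        0.070,  # E
        0.045,  # F
        0.070,  # G
        0.025,  # H
        0.055,  # I
        0.042,  # K
        0.090,  # L
        0.022,  # M
        0.045,  # N
        0.050,  # P
        0.045,  # Q
        0.042,  # R
        0.070,  # S
        0.055,  # T
        0.065,  # V
        0.014,  # W
        0.055,  # Y
    ]
)
_BACKBONE_WEIGHTS = _BACKBONE_WEIGHTS / _BACKBONE_WEIGHTS.sum()

# planted-marker interior alphabet: no C (criteria), no K/R (keeps the
# peptide fully tryptic), no P (avoids blocking the flanking cut sites).
_MARKER_INTERIOR = "ADEFGHILMNQSTVWY"


def _random_backbone(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_BACKBONE_LETTERS), size=length, p=_BACKBONE_WEIGHTS)
    return "".join(_BACKBONE_LETTERS[i] for i in idx)


def _random_marker(rng: np.random.Generator, taken: set[str]) -> str:
    """A criteria-conforming tryptic marker: 8-18 aa, no C, ends K/R."""
    while True:
        length = int(rng.integers(8, 19))
        body = "".join(
            _MARKER_INTERIOR[i]
            for i in rng.integers(0, len(_MARKER_INTERIOR), size=length - 1)
        )
        pep = body + ("K" if rng.integers(0, 2) == 0 else "R")
        if pep not in taken:
            taken.add(pep)
            return pep


def _embed(rng: np.random.Generator, peptide: str, flank: int = 30) -> str:
    """Place a peptide in tryptic context: preceded by K/R, not followed by P."""
    left = _random_backbone(rng, flank)
    left += "K" if rng.integers(0, 2) == 0 else "R"
    right = _random_backbone(rng, flank)
    if right and right[0] == "P":
        right = "A" + right[1:]
    return left + peptide + right


def make_proteomes(
    n_species: int = 9,
    planted_unique_per_species: int = 3,
    planted_shared: int = 1,
    planted_background_hits: int = 1,
    seed: int = 0,
    n_proteins: int = 20,
    species_names: Sequence[str] | None = None,
    background_matrices: Sequence[str] = ("pork", "fenugreek"),
) -> tuple[dict[str, list[ProteinRecord]], dict[str, list[ProteinRecord]], dict]:
    """Generate species proteomes and background matrices with planted truth.

    Returns ``(proteomes, backgrounds, manifest)``.  Each planted unique
    marker is criteria-conforming (8–18 aa, no C, fully tryptic, K/R-flanked)
    and embedded in exactly one species; shared peptides go into two panel
    species; background-hit peptides go into one species *and* one background
    matrix.  The manifest lists every plant plus an intensity table that
    ranks planted markers above everything else, so the selection cascade's
    expected output is fully determined.
    """
    if min(n_species, planted_unique_per_species, planted_shared,
           planted_background_hits) < 0:
        raise ValueError("counts must be >= 0")
    if planted_shared > 0 and n_species < 2:
        raise ValueError("shared peptides need at least 2 species")
    if planted_background_hits > 0 and not background_matrices:
        raise ValueError("background hits need at least one background matrix")
    if species_names is None:
        species_names = (
            list(DEFAULT_SPECIES[:n_species])
            if n_species <= len(DEFAULT_SPECIES)
            else [f"Species{i + 1}" for i in range(n_species)]
        )
    elif len(species_names) != n_species:
        raise ValueError("species_names length must equal n_species")

    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    manifest: dict = {
        "seed": seed,
        "species": list(species_names),
        "backgrounds": list(background_matrices),
        "unique": {},
        "shared": [],
        "background_hits": [],
        "intensities": {},
    }

    proteomes: dict[str, list[ProteinRecord]] = {}
    for s_i, species in enumerate(species_names):
        markers = [
            _random_marker(rng, taken) for _ in range(planted_unique_per_species)
        ]
        manifest["unique"][species] = markers
        records = []
        for p_i in range(n_proteins):
            seq = _random_backbone(rng, int(rng.integers(150, 400)))
            records.append(
                ProteinRecord(id=f"{species.replace(' ', '_')}_P{p_i + 1:02d}",
                              sequence=seq)
            )
        # each marker into its own protein -> >= 2 distinct source proteins
        for m_i, marker in enumerate(markers):
            rec = records[m_i % n_proteins]
            rec.sequence = _embed(rng, marker)
            manifest["intensities"][marker] = float(1000 - 10 * m_i - s_i)
        proteomes[species] = records

    for k in range(planted_shared):
        pep = _random_marker(rng, taken)
        a, b = species_names[k % n_species], species_names[(k + 1) % n_species]
        for sp in (a, b):
            proteomes[sp].append(
                ProteinRecord(
                    id=f"{sp.replace(' ', '_')}_SH{k + 1:02d}",
                    sequence=_embed(rng, pep),
                )
            )
        manifest["shared"].append({"peptide": pep, "species": sorted({a, b})})

    backgrounds: dict[str, list[ProteinRecord]] = {
        m: [
            ProteinRecord(
                id=f"{m}_P{i + 1:02d}",
                sequence=_random_backbone(rng, int(rng.integers(150, 400))),
            )
            for i in range(max(1, n_proteins // 4))
        ]
        for m in background_matrices
    }
    for k in range(planted_background_hits):
        pep = _random_marker(rng, taken)
        sp = species_names[k % n_species]
        matrix = background_matrices[k % len(background_matrices)]
        proteomes[sp].append(
            ProteinRecord(
                id=f"{sp.replace(' ', '_')}_BG{k + 1:02d}", sequence=_embed(rng, pep)
            )
        )
        backgrounds[matrix].append(
            ProteinRecord(id=f"{matrix}_BG{k + 1:02d}", sequence=_embed(rng, pep))
        )
        manifest["background_hits"].append(
            {"peptide": pep, "species": sp, "matrix": matrix}
        )
        manifest["intensities"][pep] = 1.0  # present but outranked

    return proteomes, backgrounds, manifest


# ---------------------------------------------------------------------------
# concentration-response tables

@dataclass
class SimulationDesign:
    """The matrix-calibration measurement design to simulate.

    Defaults mirror the standard nine-point ladder (0.1–2.5 % substitution in
    0.3 steps), four unknowns (0.0, 0.85, 1.75, 2.35 %), twelve replicate
    measurements per unknown level and multiplicative lognormal area noise
    with a 10 % CV.  Per-marker response slopes are drawn once from
    ``slope_range`` with the design's own RNG, so a design is fully
    determined by its seed.
    """

    standard_levels: tuple[float, ...] = (0.1, 0.4, 0.7, 1.0, 1.3, 1.6, 1.9, 2.2, 2.5)
    unknown_levels: tuple[float, ...] = (0.0, 0.85, 1.75, 2.35)
    replicates: int = 12  # per unknown level
    standard_replicates: int = 3
    noise_cv: float = 0.10
    markers: Mapping[str, str] | None = None  # marker -> species; None = panel-like
    slope_range: tuple[float, float] = (800.0, 4000.0)
    intercept: float = 0.0
    noise_area: float = 5.0  # baseline-noise area unit; S/N = area / noise_area
    rank_factors: tuple[float, ...] = (1.0, 0.6, 0.3)  # per-transition scaling
    seed: int = 0

    def __post_init__(self):
        if any(l < 0 for l in self.standard_levels + self.unknown_levels):
            raise ValueError("levels must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.markers is None:
            self.markers = {
                f"{sp} {i}": sp for sp in DEFAULT_SPECIES for i in (1, 2, 3)
            }


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_area_table(design: SimulationDesign) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format peak-area table for the design.

    Mean area for marker *m* at level *L* is ``slope_m · L + intercept``
    scaled per transition by ``rank_factors``, times lognormal noise of the
    stated CV; zero-level samples carry baseline noise only.  The S/N column
    is the simulated area over the design's baseline-noise unit.

    Returns ``(table, truth)`` where ``truth`` holds the per-marker slopes
    and intercepts actually used.
    """
    rng = np.random.default_rng(design.seed)
    markers = dict(design.markers)
    slopes = {
        m: float(rng.uniform(*design.slope_range)) for m in markers
    }
    rows: list[dict] = []

    def emit(sample_id: str, level: float, role: str):
        for marker, species in markers.items():
            mean = slopes[marker] * level + design.intercept
            for t_i, factor in enumerate(design.rank_factors, start=1):
                noise = float(_lognormal_factor(rng, design.noise_cv, None))
                if level > 0:
                    area = mean * factor * noise
                else:
                    area = abs(float(rng.normal(0.0, design.noise_area)))
                rows.append(
                    {
                        "sample_id": sample_id,
                        "level": level,
                        "species": species,
                        "marker": marker,
                        "transition": f"T{t_i}",
                        "area": area,
                        "snr": area / design.noise_area,
                        "role": role,
                    }
                )

    for i, level in enumerate(design.standard_levels, start=1):
        for r in range(1, design.standard_replicates + 1):
            emit(f"S{i}_r{r}", level, "standard")
    for j, level in enumerate(design.unknown_levels, start=1):
        for r in range(1, design.replicates + 1):
            emit(f"U{j}_r{r}", level, "unknown")

    truth = {"slopes": slopes, "intercept": design.intercept, "seed": design.seed}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# chromatogram traces

def simulate_chromatogram(
    t_r_s: float,
    height: float,
    width_s: float,
    noise_sd: float,
    baseline: float = 0.0,
    n_points: int = 1200,
    duration_s: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A Gaussian peak on a flat baseline with white noise.

    ``width_s`` is the Gaussian sigma in seconds.  Returns ``(t, y)``.
    """
    if width_s <= 0 or n_points <= 0:
        raise ValueError("width and n_points must be positive")
    if duration_s is None:
        duration_s = max(2.0 * t_r_s, t_r_s + 10.0 * width_s)
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    y = baseline + height * np.exp(-0.5 * ((t - t_r_s) / width_s) ** 2)
    y = y + rng.normal(0.0, noise_sd, size=n_points)
    return t, y


# ---------------------------------------------------------------------------
# formulation arithmetic

@dataclass(frozen=True)
class FormulationParams:
    """Recipe constants for the substitution arithmetic.

    ``pork_base`` is the control recipe's pork share (% of batch);
    substitution % is defined on that share.  Pork protein content defaults
    to 19.5 %.
    """

    pork_base: float = 50.0
    pork_protein_fraction: float = 0.195

    def __post_init__(self):
        if not 0 < self.pork_protein_fraction <= 1:
            raise ValueError("pork_protein_fraction must be in (0, 1]")
        if self.pork_base <= 0:
            raise ValueError("pork_base must be positive")


def flour_for_substitution(
    substitution_pct: float,
    flour_protein_fraction: float,
    params: FormulationParams = FormulationParams(),
) -> float:
    """Legume flour (% of batch) replacing ``substitution_pct`` of the meat
    protein: removed meat protein equals added legume protein."""
    if not 0 < flour_protein_fraction <= 1:
        raise ValueError("flour_protein_fraction must be in (0, 1]")
    if substitution_pct < 0:
        raise ValueError("substitution_pct must be >= 0")
    meat_protein_removed = (
        substitution_pct / 100.0 * params.pork_base * params.pork_protein_fraction
    )
    return meat_protein_removed / flour_protein_fraction


def substitution_for_flour(
    flour_pct: float,
    flour_protein_fraction: float,
    params: FormulationParams = FormulationParams(),
) -> float:
    """Inverse of :func:`flour_for_substitution`."""
    if not 0 < flour_protein_fraction <= 1:
        raise ValueError("flour_protein_fraction must be in (0, 1]")
    if flour_pct < 0:
        raise ValueError("flour_pct must be >= 0")
    return (
        flour_pct
        * flour_protein_fraction
        / (params.pork_base * params.pork_protein_fraction)
        * 100.0
    )
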