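"""Transition enumeration and scheduled-MRM method assembly.

A *transition* is a (precursor m/z, product-ion m/z) pair monitored on a
triple quadrupole; a *scheduled* method watches each marker's transitions
only inside a retention-time window, trading duty cycle for panel size.
This module enumerates the theoretically explainable a/b/y transitions of a
marker peptide, keeps the most intense ones, assembles the scheduled table,
and round-trips it through a plain CSV with full m/z re-validation.

The package ships its nine-legume reference panel (27 markers x 3
transitions, 40 s windows) as packaged data; see :func:`load_reference_panel`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import chem
from .chem import DEFAULT_CONSTANTS, Ion, MassConstants

__all__ = [
    "Transition",
    "MethodEntry",
    "MRMMethod",
    "candidate_transitions",
    "select_top_transitions",
    "build_scheduled_method",
    "concurrency_report",
    "export_transition_list",
    "import_transition_list",
    "validate_method",
    "load_reference_panel",
]

#: default product-ion m/z cutoff (strict >); low-mass fragments fall into
#: the chemical-noise region and immonium space.
MIN_PRODUCT_MZ = 250.0
#: default scheduled detection window, seconds (centered on t_R).
DEFAULT_WINDOW_S = 40.0
#: tolerance (m/z) for validating stored against recomputed values.
MZ_TOLERANCE = 0.1


@dataclass
class Transition:
    """One precursor → product ion pair with optional instrument metadata."""

    peptide: str
    precursor_mz: float
    precursor_charge: int
    product: Ion
    intensity_rank: int | None = None
    instrument_meta: dict[str, float] = field(default_factory=dict)  # DP/CE/CXP, volts

    def __post_init__(self):
        if self.precursor_charge < self.product.charge:
            raise ValueError(
                f"product charge {self.product.charge} exceeds precursor charge "
                f"{self.precursor_charge} for {self.peptide}"
            )

    @property
    def sort_key(self) -> tuple[str, int, int]:
        return (self.product.kind, self.product.index, self.product.charge)


@dataclass
class MethodEntry:
    """One marker row of a scheduled method."""

    marker: str  # e.g. "Lentil 1"
    peptide: str
    t_r_min: float | None = None
    t_r_sd_min: float | None = None
    window_s: float = DEFAULT_WINDOW_S
    transitions: list[Transition] = field(default_factory=list)  # decreasing intensity
    species: str = ""

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("detection window must be positive")

    @property
    def active_interval(self) -> tuple[float, float]:
        """Scheduled window in minutes, centered on t_R."""
        if self.t_r_min is None:
            raise ValueError(f"marker {self.marker!r} has no retention time")
        half = self.window_s / 120.0  # seconds -> minutes, halved
        return (self.t_r_min - half, self.t_r_min + half)


@dataclass
class MRMMethod:
    """A scheduled MRM method: unique marker entries plus gradient metadata."""

    entries: list[MethodEntry] = field(default_factory=list)
    gradient_min: float | None = None

    def __post_init__(self):
        names = [e.marker for e in self.entries]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def transitions(self) -> list[Transition]:
        return [t for e in self.entries for t in e.transitions]


def candidate_transitions(
    peptide: str,
    precursor_charge: int,
    series: Sequence[str] = ("a", "b", "y"),
    min_product_mz: float = MIN_PRODUCT_MZ,
    max_product_charge: int | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[Transition]:
    """All theoretically explainable fragment transitions of a peptide.

    Enumerates every requested series at every index 1..len-1 and product
    charge 1..``max_product_charge`` (default: the precursor charge), keeping
    products with m/z strictly above ``min_product_mz``.  Output order is
    deterministic: (series, index, charge).
    """
    for s in series:
        if s not in chem.SUPPORTED_SERIES:
            raise ValueError(f"unsupported ion series {s!r}")
    if max_product_charge is None:
        max_product_charge = precursor_charge
    pmz = chem.precursor_mz(peptide, precursor_charge, constants)
    out: list[Transition] = []
    for s in sorted(series):
        for index in range(1, len(peptide)):
            for z in range(1, max_product_charge + 1):
                mz = chem.fragment_mz(peptide, s, index, z, constants)
                if mz > min_product_mz:
                    out.append(
                        Transition(
                            peptide=peptide,
                            precursor_mz=pmz,
                            precursor_charge=precursor_charge,
                            product=Ion(kind=s, index=index, charge=z, mz=mz),
                        )
                    )
    return out


def select_top_transitions(
    candidates: Sequence[Transition],
    intensities: Mapping[str, float],
    n: int = 3,
) -> list[Transition]:
    """Keep the ``n`` most intense transitions, in decreasing intensity.

    ``intensities`` maps product-ion labels (e.g. ``"y5^2+"``) to measured
    abundances; candidates without an entry rank as zero.  Ties break
    deterministically by (series, index, charge).
    """
    ranked = sorted(
        candidates,
        key=lambda t: (-float(intensities.get(t.product.label, 0.0)), t.sort_key),
    )
    if n > len(ranked):
        warnings.warn(
            f"requested {n} transitions but only {len(ranked)} candidates",
            stacklevel=2,
        )
    picked = ranked[:n]
    for rank, t in enumerate(picked, start=1):
        t.intensity_rank = rank
    return picked


def build_scheduled_method(
    entries: Sequence[MethodEntry],
    window_s: float = DEFAULT_WINDOW_S,
    gradient_min: float | None = None,
) -> MRMMethod:
    """Assemble entries into a scheduled method with a common window."""
    if window_s <= 0:
        raise ValueError("detection window must be positive")
    for e in entries:
        if e.t_r_min is None:
            raise ValueError(f"marker {e.marker!r} is missing a retention time")
        e.window_s = window_s
    return MRMMethod(entries=list(entries), gradient_min=gradient_min)


def concurrency_report(method: MRMMethod) -> dict:
    """Sweep the gradient and report scheduled-transition concurrency.

    Returns ``{"max_concurrent": int, "at_time_min": float, "profile":
    [(time_min, n_active), ...]}`` where the profile gives the active
    transition count just after each window boundary.
    """
    events: list[tuple[float, int]] = []
    for e in method.entries:
        lo, hi = e.active_interval
        events.append((lo, +len(e.transitions)))
        events.append((hi, -len(e.transitions)))
    events.sort()
    profile: list[tuple[float, int]] = []
    active = 0
    best = (0, 0.0)
    i = 0
    while i < len(events):
        t = events[i][0]
        while i < len(events) and events[i][0] == t:
            active += events[i][1]
            i += 1
        profile.append((t, active))
        if active > best[0]:
            best = (active, t)
    return {"max_concurrent": best[0], "at_time_min": best[1], "profile": profile}


_CSV_COLUMNS = [
    "marker",
    "species",
    "peptide",
    "precursor_mz",
    "precursor_charge",
    "product_label",
    "product_mz",
    "t_r_min",
    "t_r_sd_min",
    "window_s",
    "dp_v",
    "ce_v",
    "cxp_v",
]


def export_transition_list(method: MRMMethod, path) -> None:
    """Write the method as a flat transition-list CSV (UTF-8, '.' decimals)."""
    rows = []
    for e in method.entries:
        for t in e.transitions:
            rows.append(
                {
                    "marker": e.marker,
                    "species": e.species,
                    "peptide": e.peptide,
                    "precursor_mz": t.precursor_mz,
                    "precursor_charge": t.precursor_charge,
                    "product_label": t.product.label,
                    "product_mz": t.product.mz,
                    "t_r_min": e.t_r_min,
                    "t_r_sd_min": e.t_r_sd_min,
                    "window_s": e.window_s,
                    "dp_v": t.instrument_meta.get("DP"),
                    "ce_v": t.instrument_meta.get("CE"),
                    "cxp_v": t.instrument_meta.get("CXP"),
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _method_from_frame(df: pd.DataFrame, window_s: float | None = None) -> MRMMethod:
    entries: list[MethodEntry] = []
    for marker, group in df.groupby("marker", sort=False):
        first = group.iloc[0]
        transitions = []
        for _, r in group.iterrows():
            series, index, charge = chem.parse_ion_label(str(r["product_label"]))
            meta = {}
            for col, key in (("dp_v", "DP"), ("ce_v", "CE"), ("cxp_v", "CXP")):
                if col in r and pd.notna(r[col]):
                    meta[key] = float(r[col])
            transitions.append(
                Transition(
                    peptide=str(first["peptide"]),
                    precursor_mz=float(r["precursor_mz"]),
                    precursor_charge=int(r["precursor_charge"]),
                    product=Ion(
                        kind=series, index=index, charge=charge,
                        mz=float(r["product_mz"]),
                    ),
                )
            )
        entries.append(
            MethodEntry(
                marker=str(marker),
                species=str(first.get("species", "")) if "species" in group else "",
                peptide=str(first["peptide"]),
                t_r_min=float(first["t_r_min"]) if pd.notna(first.get("t_r_min")) else None,
                t_r_sd_min=(
                    float(first["t_r_sd_min"])
                    if pd.notna(first.get("t_r_sd_min"))
                    else None
                ),
                window_s=(
                    window_s
                    if window_s is not None
                    else float(first.get("window_s", DEFAULT_WINDOW_S))
                ),
                transitions=transitions,
            )
        )
    return MRMMethod(entries=entries)


def validate_method(
    method: MRMMethod,
    tolerance: float = MZ_TOLERANCE,
    constants: MassConstants = DEFAULT_CONSTANTS,
    check_precursors: bool = True,
) -> list[dict]:
    """Recompute every m/z from sequence + label and list discrepancies.

    Each issue is ``{"marker", "field", "stored", "computed"}``.  An empty
    list means the stored table is self-consistent with the mass arithmetic.
    """
    issues: list[dict] = []
    for e in method.entries:
        for t in e.transitions:
            computed = chem.fragment_mz(
                e.peptide, t.product.kind, t.product.index, t.product.charge, constants
            )
            if abs(computed - t.product.mz) > tolerance:
                issues.append(
                    {
                        "marker": e.marker,
                        "field": t.product.label,
                        "stored": t.product.mz,
                        "computed": round(computed, 4),
                    }
                )
            if check_precursors:
                pmz = chem.precursor_mz(e.peptide, t.precursor_charge, constants)
                if abs(pmz - t.precursor_mz) > tolerance:
                    issues.append(
                        {
                            "marker": e.marker,
                            "field": f"precursor {t.precursor_charge}+",
                            "stored": t.precursor_mz,
                            "computed": round(pmz, 4),
                        }
                    )
    # deduplicate repeated precursor issues per marker
    seen = set()
    unique_issues = []
    for it in issues:
        key = (it["marker"], it["field"])
        if key not in seen:
            seen.add(key)
            unique_issues.append(it)
    return unique_issues


def import_transition_list(
    path,
    tolerance: float = MZ_TOLERANCE,
    constants: MassConstants = DEFAULT_CONSTANTS,
    validate: bool = True,
    window_s: float | None = None,
) -> MRMMethod:
    """Read a transition-list CSV back into an :class:`MRMMethod`.

    With ``validate`` on (default), every product m/z is recomputed from the
    peptide and ion label; a deviation beyond ``tolerance`` raises with the
    offending marker/row named.
    """
    df = pd.read_csv(path)
    missing = {"marker", "peptide", "precursor_mz", "precursor_charge",
               "product_label", "product_mz"} - set(df.columns)
    if missing:
        raise ValueError(f"transition list missing columns: {sorted(missing)}")
    method = _method_from_frame(df, window_s=window_s)
    if validate:
        issues = validate_method(
            method, tolerance=tolerance, constants=constants, check_precursors=False
        )
        if issues:
            raise ValueError(
                "product m/z validation failed: "
                + "; ".join(
                    f"{i['marker']} {i['field']} stored {i['stored']} "
                    f"vs computed {i['computed']}"
                    for i in issues
                )
            )
    return method


def load_reference_panel(window_s: float = DEFAULT_WINDOW_S) -> MRMMethod:
    """The shipped nine-legume marker panel (27 markers, 81 transitions).

    Loaded as published, without re-validation: one precursor value in the
    published table (Chickpea 3) is an average-mass figure that deviates from
    the monoisotopic value by ~0.44 m/z; :func:`validate_method` reports it.
    """
    ref = resources.files("mrmkit.data").joinpath("legume_panel.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return _method_from_frame(df, window_s=window_s)
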