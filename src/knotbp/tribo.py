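"""Triboelectric sensor output model and bench-characterization statistics.

A single-electrode triboelectric pair (e.g. PET donor / PTFE acceptor)
develops an open-circuit voltage

    V = −Q_t/(A_a·ε) · (d_t + D) + σ·D/ε,      Q_t = A_e·(Ŵ₁ − Ŵ₂)

where Q_t is the tribo-charge on the dielectric surface, A_e/A_a the
effective (total contact) and apparent (projected) areas, Ŵ the material
work functions, d_t the combined layer thickness, D the gap and ε the
gap permittivity. For two units built from the same materials with equal
gap, thickness and apparent area, the voltage ratio collapses to the
tribo-charge ratio and hence to the effective-area ratio — which is how
a multi-stacked box-knot geometry buys output: repeated knotting piles
up contact area while the top-view footprint stays small.

Also included are the bench statistics used to characterize such a
sensor: stored energy on a load capacitor, areal power density,
pressure-sensitivity slope, pressure resolution from replicate
separation, and loading/unloading hysteresis error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TriboMaterial:
    """A triboelectric layer: name, work function and layer thickness."""

    name: str
    work_function: float  # energy units (per unit charge·area in the model)
    thickness: float  # m

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class TriboPairConfig:
    """Geometry and material parameters of one contact-separation unit.

    effective_area ≥ apparent_area: the stacked contact surface can only
    exceed the projected footprint.
    """

    donor: TriboMaterial
    acceptor: TriboMaterial
    effective_area: float  # m², A_e
    apparent_area: float  # m², A_a
    surface_charge_density: float  # C/m², σ
    gap: float  # m, D
    permittivity: float  # F/m, ε

    def __post_init__(self) -> None:
        if not self.effective_area >= self.apparent_area > 0:
            raise ValueError("need effective_area >= apparent_area > 0")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.permittivity <= 0:
            raise ValueError("permittivity must be positive")

    @property
    def layer_thickness(self) -> float:
        """Combined thickness d_t of the two triboelectric layers."""
        return self.donor.thickness + self.acceptor.thickness


def tribo_charge(cfg: TriboPairConfig) -> float:
    """Tribo-charge Q_t = A_e·(Ŵ₁ − Ŵ₂); sign follows the donor→acceptor
    work-function ordering."""
    return cfg.effective_area * (
        cfg.donor.work_function - cfg.acceptor.work_function
    )


def open_circuit_voltage(cfg: TriboPairConfig) -> float:
    """Open-circuit voltage of the two-term single-electrode model."""
    qt = tribo_charge(cfg)
    return (
        -qt / (cfg.apparent_area * cfg.permittivity) * (cfg.layer_thickness + cfg.gap)
        + cfg.surface_charge_density * cfg.gap / cfg.permittivity
    )


def voltage_ratio(box: TriboPairConfig, plane: TriboPairConfig) -> float:
    """Estimated output ratio V_box/V_plane = Q_t,box/Q_t,plane.

    Valid only for units sharing materials, gap, layer thickness and
    apparent area; violating that contract raises, because the ratio no
    longer reduces to the effective-area ratio.
    """
    shared = [
        ("gap", box.gap, plane.gap),
        ("permittivity", box.permittivity, plane.permittivity),
        ("apparent_area", box.apparent_area, plane.apparent_area),
        ("layer_thickness", box.layer_thickness, plane.layer_thickness),
        ("surface_charge_density",
         box.surface_charge_density, plane.surface_charge_density),
        ("donor work function",
         box.donor.work_function, plane.donor.work_function),
        ("acceptor work function",
         box.acceptor.work_function, plane.acceptor.work_function),
    ]
    for name, vb, vp in shared:
        if vb != vp:
            raise ValueError(
                f"voltage_ratio requires equal {name}: {vb} != {vp}"
            )
    qp = tribo_charge(plane)
    if qp == 0:
        raise ValueError("plane unit has zero tribo-charge")
    return tribo_charge(box) / qp


def knot_areas(
    top_side_mm: float, knot_layers: int, second_layer_contact: bool
) -> tuple[float, float]:
    """Apparent and effective areas (mm²) of a box-knot sensing unit.

    Each knotting layer contributes one top-plane area to the apparent
    (stacked contact) area; when the second layer makes an additional
    up-and-down contact pair it adds one further top-plane area to the
    effective area. With a 15 mm top side and three knottings this gives
    675 mm² apparent and 900 mm² effective area. The second-layer term
    is an inferred geometric model, not a measured quantity.
    """
    if top_side_mm <= 0:
        raise ValueError("top side must be positive")
    if knot_layers < 1:
        raise ValueError("need at least one knotting layer")
    plane = top_side_mm**2
    apparent = knot_layers * plane
    effective = apparent + (plane if second_layer_contact else 0.0)
    return apparent, effective


def enhancement_percent(v_test: float, v_control: float) -> dict:
    """Relative output difference under both baseline conventions.

    ``vs_control``: 100·(V_test − V_control)/V_control;
    ``vs_test``:    100·(V_test − V_control)/V_test.
    Reported measured enhancements are ambiguous about the baseline, so
    both are returned.
    """
    if v_control == 0 or v_test == 0:
        raise ValueError("voltages must be nonzero")
    return {
        "vs_control": 100.0 * (v_test - v_control) / v_control,
        "vs_test": 100.0 * (v_test - v_control) / v_test,
    }


def stored_energy(capacitance: float, voltage: float) -> float:
    """Energy E = C·U²/2 stored on a load capacitor, in joules."""
    if capacitance <= 0:
        raise ValueError("capacitance must be positive")
    return 0.5 * capacitance * voltage**2


def power_density(voltages, resistance: float, area: float) -> float:
    """Peak areal power max(V²)/(R·A) over a voltage series, W/m²."""
    if resistance <= 0:
        raise ValueError("load resistance must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    v = np.asarray(voltages, dtype=float)
    if v.size == 0:
        raise ValueError("empty voltage series")
    return float(np.max(v**2) / (resistance * area))


def sensitivity_fit(voc, pressure_kpa, linear_max_kpa: float = 0.44) -> float:
    """Pressure sensitivity in mV/Pa from the linear low-pressure range.

    OLS slope of open-circuit voltage (V) against pressure, restricted
    to points with pressure ≤ ``linear_max_kpa`` (the upper end of the
    linear response region), converted to mV per Pa.
    """
    voc = np.asarray(voc, dtype=float)
    p = np.asarray(pressure_kpa, dtype=float)
    if voc.shape != p.shape:
        raise ValueError("voltage and pressure series must be aligned")
    sel = p <= linear_max_kpa
    if np.sum(sel) < 2:
        raise ValueError("need at least two points in the linear range")
    p_pa = p[sel] * 1000.0
    if np.ptp(p_pa) == 0:
        raise ValueError("zero pressure variance in the linear range")
    slope_v_per_pa = np.polyfit(p_pa, voc[sel], 1)[0]
    return float(slope_v_per_pa * 1000.0)  # V/Pa → mV/Pa


#: sentinel returned when no grid spacing separates adjacent steps
NO_RESOLUTION = float("inf")


def resolution_estimate(
    pressure_steps_kpa, voc_replicates, k: float = 2.0
) -> tuple[float, list[int]]:
    """Smallest pressure interval giving a distinctive V_oc change.

    ``voc_replicates`` holds ≥2 replicate voltages per pressure step.
    Adjacent steps are *separated* when the gap of their replicate means
    exceeds ``k`` pooled standard deviations. Returns the smallest step
    interval whose endpoints separate (``NO_RESOLUTION`` if none does)
    and the indices of non-separating ("ineffective") intervals.
    """
    p = np.asarray(pressure_steps_kpa, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two pressure steps")
    if np.any(np.diff(p) <= 0):
        raise ValueError("pressure grid must be strictly increasing")
    reps = [np.asarray(r, dtype=float) for r in voc_replicates]
    if len(reps) != p.size or any(r.size < 2 for r in reps):
        raise ValueError("need >=2 replicates for every pressure step")

    best = NO_RESOLUTION
    ineffective = []
    for i in range(p.size - 1):
        gap = abs(np.mean(reps[i + 1]) - np.mean(reps[i]))
        pooled = np.sqrt(0.5 * (np.var(reps[i], ddof=1) + np.var(reps[i + 1], ddof=1)))
        if gap > k * pooled:
            best = min(best, p[i + 1] - p[i])
        else:
            ineffective.append(i)
    return float(best), ineffective


def hysteresis_error(loading, unloading) -> float:
    """Loading/unloading hysteresis as percent of full-scale voltage.

    Both arguments are (pressure, voltage) pairs. The curves are
    linearly interpolated onto their common pressure range; the error is
    the maximum absolute voltage gap divided by the full-scale (maximum
    loading-curve) voltage, ×100.
    """
    pl, vl = (np.asarray(a, dtype=float) for a in zip(*loading))
    pu, vu = (np.asarray(a, dtype=float) for a in zip(*unloading))
    ol = np.argsort(pl)
    ou = np.argsort(pu)
    pl, vl, pu, vu = pl[ol], vl[ol], pu[ou], vu[ou]
    lo, hi = max(pl[0], pu[0]), min(pl[-1], pu[-1])
    if hi <= lo:
        raise ValueError("loading and unloading pressure ranges do not overlap")
    grid = np.union1d(pl, pu)
    grid = grid[(grid >= lo) & (grid <= hi)]
    gap = np.abs(np.interp(grid, pl, vl) - np.interp(grid, pu, vu))
    full_scale = np.max(np.abs(vl))
    if full_scale == 0:
        raise ValueError("flat loading curve: full scale undefined")
    return float(100.0 * np.max(gap) / full_scale)
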