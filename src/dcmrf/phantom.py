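"""Digital vial phantoms with known per-vial agent concentrations.

The default phantom emulates a 17-vial bench study: five Gd-only dilutions
(0.05-0.5 mM), five Mn-only dilutions (0.0125-0.2 mM), six Gd+Mn mixtures
(Gd 0.025-0.355 mM, Mn 0.00625-0.15 mM) and one water-only vial, arranged
in four rows (mixtures on the top two rows, Mn-only third, Gd-only bottom).
The exact bench concentrations are representative values evenly spaced
between the published endpoints of each dilution series; user-supplied
tables load through :func:`dcmrf.io.read_phantom_spec`.

Rendering a phantom produces ground-truth concentration maps plus either a
relaxation-time table (for the relaxometry arm) or a per-pixel complex MRF
signal series with complex Gaussian noise (for the imaging arm), so every
downstream stage is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import InputDomainError
from .presets import GD_3T_MRF, MN_3T_MRF, WATER_3T_MRF
from .relaxation import forward_relaxation
from .types import AgentRelaxivity, BaselineRelaxation, ConcentrationPair
from .mrf import MRFSchedule, simulate_fisp_batch, DEFAULT_N_STATES

__all__ = [
    "Vial",
    "PhantomSpec",
    "TruthMaps",
    "default_phantom_table",
    "default_concentrations",
    "render_truth_maps",
    "simulate_mrf_series",
    "repeat_study",
]

#: Representative dilution series hitting the published range endpoints (mM).
GD_ONLY_SERIES = (0.05, 0.1, 0.2, 0.35, 0.5)
MN_ONLY_SERIES = (0.0125, 0.025, 0.05, 0.1, 0.2)
MIX_GD_SERIES = tuple(np.round(np.linspace(0.025, 0.355, 6), 6))
MIX_MN_SERIES = tuple(np.round(np.linspace(0.00625, 0.15, 6), 6))


@dataclass(frozen=True)
class Vial:
    """One cylindrical vial: id, center (row, col) px, radius px, concentrations."""

    vial_id: int
    center: tuple
    radius: float
    conc: ConcentrationPair

    def __post_init__(self):
        if self.radius <= 0:
            raise InputDomainError("vial radius must be > 0")
        if self.vial_id < 1:
            raise InputDomainError("vial_id must be >= 1 (0 is background)")


@dataclass(frozen=True)
class PhantomSpec:
    """Vial layout plus the physics needed to render it (baseline + agents)."""

    image_shape: tuple
    vials: tuple
    baseline: BaselineRelaxation
    agents: tuple  # (AgentRelaxivity for the Gd role, for the Mn role)

    def __post_init__(self):
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise InputDomainError("image_shape must be positive")
        ids = [v.vial_id for v in self.vials]
        if len(set(ids)) != len(ids):
            raise InputDomainError("vial_ids must be unique")
        for v in self.vials:
            r, c = v.center
            if not (v.radius <= r <= rows - 1 - v.radius
                    and v.radius <= c <= cols - 1 - v.radius):
                raise InputDomainError(f"vial {v.vial_id} extends outside the image")
        for i, va in enumerate(self.vials):
            for vb in self.vials[i + 1:]:
                dist = np.hypot(va.center[0] - vb.center[0],
                                va.center[1] - vb.center[1])
                if dist <= va.radius + vb.radius:
                    raise InputDomainError(
                        f"vials {va.vial_id} and {vb.vial_id} overlap")
        object.__setattr__(self, "vials", tuple(self.vials))

    def relaxation_times(self):
        """Per-vial (T1, T2) from the dual-agent forward model, in vial order."""
        return [forward_relaxation(self.baseline, self.agents[0], self.agents[1],
                                   v.conc) for v in self.vials]


@dataclass(frozen=True)
class TruthMaps:
    """Ground-truth per-pixel concentration maps and integer vial labels."""

    gd_map: np.ndarray
    mn_map: np.ndarray
    roi_labels: np.ndarray


def default_concentrations():
    """The 17 (vial_id, gd mM, mn mM) triples of the default phantom."""
    triples = []
    vid = 1
    for gd in GD_ONLY_SERIES:
        triples.append((vid, gd, 0.0)); vid += 1
    for mn in MN_ONLY_SERIES:
        triples.append((vid, 0.0, mn)); vid += 1
    for gd, mn in zip(MIX_GD_SERIES, MIX_MN_SERIES):
        triples.append((vid, gd, mn)); vid += 1
    triples.append((vid, 0.0, 0.0))  # deionized water only
    return triples


def default_phantom_table(image_shape=(128, 128), radius: float | None = None,
                          baseline: BaselineRelaxation = WATER_3T_MRF,
                          agents=(GD_3T_MRF, MN_3T_MRF)) -> PhantomSpec:
    """The 17-vial default phantom laid out in four rows.

    Bottom row: the five Gd-only vials; third row: the five Mn-only vials;
    top two rows: the six mixtures, with the water-only vial closing the top
    row.  The default 128x128 canvas keeps simulations desk-scale; pass a
    larger ``image_shape`` (e.g. 352x352) for full-size maps.
    """
    rows, cols = image_shape
    if radius is None:
        radius = 0.07 * min(rows, cols)
    conc = default_concentrations()
    gd_only, mn_only = conc[0:5], conc[5:10]
    mixtures, water = conc[10:16], conc[16]

    row_y = [int(round(f * rows)) for f in (0.125, 0.375, 0.625, 0.875)]
    col_x5 = [int(round(f * cols)) for f in (0.125, 0.3125, 0.5, 0.6875, 0.875)]
    col_x4 = [int(round(f * cols)) for f in (0.155, 0.385, 0.615, 0.845)]

    vials = []
    # Top row: mixtures 4-6 + water.
    for (entry, x) in zip(mixtures[3:] + [water], col_x4):
        vials.append(Vial(entry[0], (row_y[0], x), radius,
                          ConcentrationPair(entry[1], entry[2])))
    # Second row: mixtures 1-3.
    for (entry, x) in zip(mixtures[:3], col_x4[:3]):
        vials.append(Vial(entry[0], (row_y[1], x), radius,
                          ConcentrationPair(entry[1], entry[2])))
    # Third row: Mn-only; bottom row: Gd-only.
    for (entry, x) in zip(mn_only, col_x5):
        vials.append(Vial(entry[0], (row_y[2], x), radius,
                          ConcentrationPair(entry[1], entry[2])))
    for (entry, x) in zip(gd_only, col_x5):
        vials.append(Vial(entry[0], (row_y[3], x), radius,
                          ConcentrationPair(entry[1], entry[2])))
    vials.sort(key=lambda v: v.vial_id)
    return PhantomSpec(image_shape=tuple(image_shape), vials=tuple(vials),
                       baseline=baseline, agents=tuple(agents))


def render_truth_maps(spec: PhantomSpec) -> TruthMaps:
    """Rasterize the vials: a pixel belongs to a vial iff its center lies
    within the vial radius (inclusive)."""
    rows, cols = spec.image_shape
    gd = np.zeros((rows, cols))
    mn = np.zeros((rows, cols))
    labels = np.zeros((rows, cols), dtype=int)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for v in spec.vials:
        inside = (rr - v.center[0]) ** 2 + (cc - v.center[1]) ** 2 <= v.radius ** 2
        gd[inside] = v.conc.agent_a
        mn[inside] = v.conc.agent_b
        labels[inside] = v.vial_id
    return TruthMaps(gd_map=gd, mn_map=mn, roi_labels=labels)


def simulate_mrf_series(spec: PhantomSpec, sched: MRFSchedule,
                        noise_sd: float = 0.0, seed: int | None = None,
                        n_states: int = DEFAULT_N_STATES):
    """Per-pixel complex MRF signal series for a phantom.

    Each vial's (T1, T2) comes from the dual-agent forward model; its pixels
    carry the corresponding FISP signal evolution.  Background pixels are
    zero.  Complex Gaussian noise with standard deviation
    ``noise_sd * max |signal|`` (split evenly between the real and imaginary
    channels) is added everywhere.  Deterministic given the seed.

    Returns ``(series, truth)`` with ``series`` of shape (rows, cols, N).
    """
    if noise_sd < 0:
        raise InputDomainError("noise_sd must be >= 0")
    truth = render_truth_maps(spec)
    rows, cols = spec.image_shape
    n = len(sched)
    times = spec.relaxation_times()
    signals = simulate_fisp_batch([t.T1 for t in times], [t.T2 for t in times],
                                  sched, n_states)
    series = np.zeros((rows, cols, n), dtype=complex)
    for v, sig in zip(spec.vials, signals):
        series[truth.roi_labels == v.vial_id] = sig
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        sd = noise_sd * np.max(np.abs(signals)) / np.sqrt(2.0)
        series += rng.normal(0.0, sd, series.shape) \
            + 1j * rng.normal(0.0, sd, series.shape)
    return series, truth


def repeat_study(spec: PhantomSpec, sched: MRFSchedule, noise_sd: float,
                 n_repeats: int, seed: int | None = None,
                 reposition_px: int = 2, n_states: int = DEFAULT_N_STATES):
    """Repeat the acquisition with independent noise and optional repositioning.

    Repositioning translates the whole vial rack rigidly by a uniform integer
    offset in [-reposition_px, reposition_px] per axis per repeat (0 disables
    it).  Returns a list of ``(series, truth)`` pairs; each repeat's truth
    reflects its own repositioned geometry.
    """
    if n_repeats < 1:
        raise InputDomainError("n_repeats must be >= 1")
    ss = np.random.SeedSequence(seed)
    results = []
    for child in ss.spawn(n_repeats):
        rng = np.random.default_rng(child)
        moved = spec
        if reposition_px > 0:
            dr, dc = rng.integers(-reposition_px, reposition_px + 1, size=2)
            moved = replace(spec, vials=tuple(
                replace(v, center=(v.center[0] + int(dr), v.center[1] + int(dc)))
                for v in spec.vials))
        results.append(simulate_mrf_series(moved, sched, noise_sd, rng, n_states))
    return results
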