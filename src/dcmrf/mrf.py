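"""FISP-MRF simulation, dictionary generation, and inner-product matching.

The fingerprinting acquisition plays out N gradient-echo excitations with
deliberately varying flip angle and repetition time after a non-selective
inversion preparation.  Each (T1, T2) pair traces a distinctive signal
evolution; a dictionary of simulated evolutions over a (T1, T2) grid is
matched to measured per-voxel signals by maximizing the magnitude of the
normalized complex inner product, yielding co-registered T1 and T2 maps in
a single pass.

Signal model
------------
The FISP kernel (unbalanced gradient each TR, constant RF phase, no RF
spoiling) is simulated with the extended phase graph (EPG) formalism: the
magnetization is tracked as configuration states F+(k), F-(k), Z(k) over
dephasing orders k.  Per TR: an RF rotation mixes the states, the echo is
the F0 state decayed to the echo time, then relaxation acts over the TR and
the unbalanced gradient shifts every F state by one order.  The recursion is
exact for this discrete-gradient model when the truncation order exceeds the
number of pulses, and accurate far below that because repeated T2 decay and
partial flips suppress high orders.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from ._exceptions import InputDomainError
from .types import RelaxationTimes

__all__ = [
    "MRFSchedule",
    "DictionaryGrid",
    "MRFDictionary",
    "MatchResult",
    "make_default_schedule",
    "expand_grid",
    "simulate_fisp",
    "simulate_fisp_batch",
    "build_dictionary",
    "match",
    "match_map",
    "DEFAULT_N_STATES",
]

#: Default EPG truncation order (number of retained configuration orders).
DEFAULT_N_STATES = 100


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MRFSchedule:
    """Per-excitation flip angles (deg) and repetition times (ms), plus prep.

    ``inversion_time`` is the delay between the inversion pulse and the first
    excitation; ``echo_time`` the delay from each excitation to its readout;
    ``inversion_efficiency`` scales the ideal 180 degree inversion.
    """

    flip_angles_deg: np.ndarray
    repetition_times_ms: np.ndarray
    inversion_time_ms: float = 21.0
    echo_time_ms: float = 2.0
    inversion_efficiency: float = 1.0

    def __post_init__(self):
        fa = np.ascontiguousarray(self.flip_angles_deg, dtype=float)
        tr = np.ascontiguousarray(self.repetition_times_ms, dtype=float)
        if fa.ndim != 1 or fa.shape != tr.shape or fa.size < 1:
            raise InputDomainError("flip angle and TR arrays must be equal-length 1-D, N >= 1")
        if np.any(tr <= 0):
            raise InputDomainError("all repetition times must be > 0")
        if not 0 < self.echo_time_ms < tr.min():
            raise InputDomainError("echo_time must satisfy 0 < TE < min(TR)")
        if self.inversion_time_ms < 0:
            raise InputDomainError("inversion_time must be >= 0")
        if not 0 <= self.inversion_efficiency <= 1:
            raise InputDomainError("inversion_efficiency must be in [0, 1]")
        fa.setflags(write=False)
        tr.setflags(write=False)
        object.__setattr__(self, "flip_angles_deg", fa)
        object.__setattr__(self, "repetition_times_ms", tr)

    def __len__(self) -> int:
        return self.flip_angles_deg.size

    @property
    def duration_ms(self) -> float:
        return float(self.inversion_time_ms + self.repetition_times_ms.sum())

    def fingerprint(self) -> str:
        """SHA-256 of the schedule contents; identifies the dictionary's provenance."""
        h = hashlib.sha256()
        h.update(np.round(self.flip_angles_deg, 9).tobytes())
        h.update(np.round(self.repetition_times_ms, 9).tobytes())
        h.update(np.float64([self.inversion_time_ms, self.echo_time_ms,
                             self.inversion_efficiency]).tobytes())
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {
            "flip_angles_deg": self.flip_angles_deg.tolist(),
            "repetition_times_ms": self.repetition_times_ms.tolist(),
            "inversion_time_ms": self.inversion_time_ms,
            "echo_time_ms": self.echo_time_ms,
            "inversion_efficiency": self.inversion_efficiency,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MRFSchedule":
        return cls(
            flip_angles_deg=np.asarray(d["flip_angles_deg"], float),
            repetition_times_ms=np.asarray(d["repetition_times_ms"], float),
            inversion_time_ms=float(d.get("inversion_time_ms", 21.0)),
            echo_time_ms=float(d.get("echo_time_ms", 2.0)),
            inversion_efficiency=float(d.get("inversion_efficiency", 1.0)),
        )


def make_default_schedule(n: int = 3000, baseline_tr: float = 12.0,
                          seed: int = 0, *, lobe_length: int = 200,
                          max_flip_deg: float = 75.0,
                          inversion_time_ms: float = 21.0,
                          echo_time_ms: float = 2.0) -> MRFSchedule:
    """Default fingerprinting schedule: sinusoidal flip-angle lobes over a
    smoothly perturbed TR train.

    Flip angles follow repeating half-sinusoid lobes of ``lobe_length``
    excitations whose peak amplitudes vary pseudo-randomly up to
    ``max_flip_deg``; TR is ``baseline_tr`` plus a smooth positive
    perturbation bounded by 3 ms.  Deterministic for a given seed.  Any
    published waveform can be used instead by constructing
    :class:`MRFSchedule` directly or loading it from JSON.
    """
    if n < 1:
        raise InputDomainError("n must be >= 1")
    rng = np.random.default_rng(seed)

    n_lobes = int(np.ceil(n / lobe_length))
    # Alternate high/low lobe peaks so successive lobes differ in weighting.
    highs = rng.uniform(0.7, 1.0, n_lobes) * max_flip_deg
    lows = rng.uniform(0.35, 0.6, n_lobes) * max_flip_deg
    peaks = np.where(np.arange(n_lobes) % 2 == 0, highs, lows)
    idx = np.arange(n)
    pos = idx % lobe_length
    fa = peaks[idx // lobe_length] * np.sin(np.pi * (pos + 0.5) / lobe_length)

    # Smooth positive TR perturbation in [0, 3) ms: low-pass filtered noise.
    raw = rng.uniform(0.0, 1.0, n + 100)
    kernel = np.hanning(101)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="valid")[:n]
    if n > 1 and np.ptp(smooth) > 0:
        smooth = (smooth - smooth.min()) / np.ptp(smooth)
    else:
        smooth = np.zeros(n)
    tr = baseline_tr + 3.0 * smooth

    return MRFSchedule(flip_angles_deg=fa, repetition_times_ms=tr,
                       inversion_time_ms=inversion_time_ms,
                       echo_time_ms=echo_time_ms)


# ---------------------------------------------------------------------------
# Dictionary grid
# ---------------------------------------------------------------------------

_DEFAULT_T1_SEGMENTS = ((10, 100, 10), (100, 1000, 20), (1000, 2000, 40), (2000, 4500, 100))
_DEFAULT_T2_SEGMENTS = ((2, 100, 2), (100, 150, 5), (160, 300, 10),
                        (300, 800, 50), (800, 1600, 100), (1600, 3000, 200))

_COARSE_T1_SEGMENTS = ((20, 100, 20), (100, 1000, 60), (1000, 3000, 250))
_COARSE_T2_SEGMENTS = ((5, 100, 10), (100, 300, 40), (300, 1200, 150))


@dataclass(frozen=True)
class DictionaryGrid:
    """Piecewise-uniform (T1, T2) grid specification.

    Each segment is ``(start_ms, stop_ms, step_ms)``; boundary values shared
    between consecutive segments are counted once.  With ``t2_le_t1`` set
    (default), unphysical T2 > T1 combinations are removed.
    """

    t1_segments: tuple = _DEFAULT_T1_SEGMENTS
    t2_segments: tuple = _DEFAULT_T2_SEGMENTS
    t2_le_t1: bool = True

    def __post_init__(self):
        for axis, segments in (("T1", self.t1_segments), ("T2", self.t2_segments)):
            if not segments:
                raise InputDomainError(f"{axis} needs at least one segment")
            prev_stop = -np.inf
            for start, stop, step in segments:
                if step <= 0 or stop < start or start <= 0:
                    raise InputDomainError(
                        f"invalid {axis} segment ({start}, {stop}, {step})")
                if start < prev_stop:
                    raise InputDomainError(f"{axis} segments overlap at {start}")
                prev_stop = stop
        object.__setattr__(self, "t1_segments",
                           tuple(tuple(float(x) for x in s) for s in self.t1_segments))
        object.__setattr__(self, "t2_segments",
                           tuple(tuple(float(x) for x in s) for s in self.t2_segments))

    @classmethod
    def default(cls, t2_le_t1: bool = True) -> "DictionaryGrid":
        """The full acquisition grid: T1 10-4500 ms, T2 2-3000 ms, fine steps."""
        return cls(_DEFAULT_T1_SEGMENTS, _DEFAULT_T2_SEGMENTS, t2_le_t1)

    @classmethod
    def coarse(cls, t2_le_t1: bool = True) -> "DictionaryGrid":
        """A reduced grid covering the same ranges with coarser steps, for
        fast exploratory runs and self-tests."""
        return cls(_COARSE_T1_SEGMENTS, _COARSE_T2_SEGMENTS, t2_le_t1)

    def to_dict(self) -> dict:
        return {"t1_segments": [list(s) for s in self.t1_segments],
                "t2_segments": [list(s) for s in self.t2_segments],
                "t2_le_t1": self.t2_le_t1}

    @classmethod
    def from_dict(cls, d: dict) -> "DictionaryGrid":
        return cls(tuple(tuple(s) for s in d["t1_segments"]),
                   tuple(tuple(s) for s in d["t2_segments"]),
                   bool(d.get("t2_le_t1", True)))


def _axis_values(segments) -> np.ndarray:
    values = np.concatenate([
        np.arange(start, stop + step / 2, step) for start, stop, step in segments
    ])
    # De-duplicate shared segment boundaries; round kills float arange jitter.
    return np.unique(np.round(values, 6))


def expand_grid(grid: DictionaryGrid) -> np.ndarray:
    """All retained (T1, T2) pairs of a grid, shape (M, 2), sorted by T1 then T2."""
    t1_values = _axis_values(grid.t1_segments)
    t2_values = _axis_values(grid.t2_segments)
    t1_mesh, t2_mesh = np.meshgrid(t1_values, t2_values, indexing="ij")
    pairs = np.column_stack([t1_mesh.ravel(), t2_mesh.ravel()])
    if grid.t2_le_t1:
        pairs = pairs[pairs[:, 1] <= pairs[:, 0]]
    if pairs.size == 0:
        raise InputDomainError("grid expansion is empty")
    return pairs


# ---------------------------------------------------------------------------
# EPG simulation
# ---------------------------------------------------------------------------

def _rf_operator(alpha_rad: float) -> np.ndarray:
    """EPG mixing matrix of an RF pulse of flip ``alpha`` about a fixed (x) axis,
    acting on the state triple (F+(k), F-~(k), Z(k)) for every order k."""
    a2 = alpha_rad / 2.0
    c2, s2 = np.cos(a2) ** 2, np.sin(a2) ** 2
    sa, ca = np.sin(alpha_rad), np.cos(alpha_rad)
    return np.array([
        [c2, s2, -1j * sa],
        [s2, c2, 1j * sa],
        [-0.5j * sa, 0.5j * sa, ca],
    ], dtype=complex)


def simulate_fisp_batch(t1, t2, sched: MRFSchedule,
                        n_states: int = DEFAULT_N_STATES) -> np.ndarray:
    """EPG signal evolutions for many (T1, T2) pairs at once.

    Parameters
    ----------
    t1, t2 : array-like, shape (M,)
        Relaxation times, ms.  T2 > T1 is simulated if requested (the grid
        filter normally removes such pairs; see :func:`expand_grid`).
    sched : MRFSchedule
    n_states : int
        EPG truncation order (>= 2); orders above it are discarded each TR.

    Returns
    -------
    ndarray, complex, shape (M, N)
        The F0 configuration sampled at the echo time of each excitation.
    """
    t1 = np.atleast_1d(np.asarray(t1, float))
    t2 = np.atleast_1d(np.asarray(t2, float))
    if t1.shape != t2.shape or t1.ndim != 1:
        raise InputDomainError("t1 and t2 must be equal-length 1-D")
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise InputDomainError("T1/T2 must be finite")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise InputDomainError("T1/T2 must be > 0")
    if n_states < 2:
        raise InputDomainError("n_states must be >= 2")

    m = t1.size
    n = len(sched)
    fa = np.deg2rad(sched.flip_angles_deg)
    tr = sched.repetition_times_ms
    te = sched.echo_time_ms

    # State matrix: rows (F+, F-~, Z) x orders x entries.
    state = np.zeros((3, n_states, m), dtype=complex)
    # Ideal inversion of thermal equilibrium, then recovery over the prep delay.
    z0 = -sched.inversion_efficiency
    e1_ti = np.exp(-sched.inversion_time_ms / t1)
    state[2, 0] = 1.0 + (z0 - 1.0) * e1_ti

    e2_te = np.exp(-te / t2)
    e1_tr = np.exp(-tr[:, None] / t1[None, :])
    e2_tr = np.exp(-tr[:, None] / t2[None, :])

    out = np.empty((m, n), dtype=complex)
    flat = state.reshape(3, n_states * m)
    for i in range(n):
        flat[:] = np.matmul(_rf_operator(fa[i]), flat)
        out[:, i] = state[0, 0] * e2_te
        # Relaxation over the full TR (echo sampling above already applied the
        # TE portion to the recorded value; states evolve with the TR total).
        state[0] *= e2_tr[i]
        state[1] *= e2_tr[i]
        state[2] *= e1_tr[i]
        state[2, 0] += 1.0 - e1_tr[i]
        # Unbalanced gradient: shift every F configuration by one order.
        state[0, 1:] = state[0, :-1]
        state[1, :-1] = state[1, 1:]
        state[1, -1] = 0.0
        state[0, 0] = np.conj(state[1, 0])
    return out


def simulate_fisp(T1: float, T2: float, sched: MRFSchedule,
                  n_states: int = DEFAULT_N_STATES) -> np.ndarray:
    """Single-voxel FISP signal evolution; see :func:`simulate_fisp_batch`."""
    return simulate_fisp_batch([T1], [T2], sched, n_states)[0]


# ---------------------------------------------------------------------------
# Dictionary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MRFDictionary:
    """Unit-norm simulated signal evolutions indexed by (T1, T2).

    ``atoms`` has shape (entries, timepoints) with each row normalized to
    unit Euclidean norm; ``lookup`` has shape (entries, 2) holding the
    generating (T1 ms, T2 ms), sorted by T1 then T2 so that matching ties
    break deterministically.
    """

    atoms: np.ndarray
    lookup: np.ndarray
    schedule_fingerprint: str
    grid: DictionaryGrid | None = None

    def __post_init__(self):
        if self.atoms.shape[0] != self.lookup.shape[0]:
            raise InputDomainError("atoms and lookup must have one row per entry")

    def __len__(self) -> int:
        return self.atoms.shape[0]

    def save(self, path) -> None:
        """Persist to HDF5 (atoms, lookup, schedule fingerprint, grid spec)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("atoms", data=self.atoms, compression="gzip")
            f.create_dataset("lookup", data=self.lookup)
            f.attrs["schedule_fingerprint"] = self.schedule_fingerprint
            if self.grid is not None:
                f.attrs["grid_json"] = json.dumps(self.grid.to_dict())

    @classmethod
    def load(cls, path) -> "MRFDictionary":
        with h5py.File(path, "r") as f:
            grid_json = f.attrs.get("grid_json")
            return cls(
                atoms=f["atoms"][...],
                lookup=f["lookup"][...],
                schedule_fingerprint=str(f.attrs["schedule_fingerprint"]),
                grid=DictionaryGrid.from_dict(json.loads(grid_json))
                if grid_json else None,
            )


def build_dictionary(grid: DictionaryGrid, sched: MRFSchedule,
                     n_states: int = DEFAULT_N_STATES,
                     batch_size: int = 2000) -> MRFDictionary:
    """Simulate and unit-normalize one atom per retained grid pair.

    Deterministic; atoms whose simulated norm is numerically zero are
    rejected and reported in the raised error together with their (T1, T2).
    """
    pairs = expand_grid(grid)
    chunks = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        chunks.append(simulate_fisp_batch(chunk[:, 0], chunk[:, 1], sched, n_states))
    atoms = np.vstack(chunks)
    norms = np.linalg.norm(atoms, axis=1)
    dead = norms <= atoms.shape[1] * np.finfo(float).eps
    if np.any(dead):
        raise InputDomainError(
            f"zero-norm dictionary atoms for (T1,T2) pairs: {pairs[dead].tolist()}")
    atoms = atoms / norms[:, None]
    return MRFDictionary(atoms=atoms, lookup=pairs,
                         schedule_fingerprint=sched.fingerprint(), grid=grid)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Best dictionary entry for one voxel.

    ``match_coefficient`` is |<atom, signal/|signal|>| in [0, 1]; ``scale``
    is |<atom, raw signal>|, a proton-density proxy.  ``valid`` is False for
    zero-norm (background) signals, in which case T1 = T2 = 0.
    """

    T1: float
    T2: float
    match_coefficient: float
    scale: float
    valid: bool = True


def _match_block(signals: np.ndarray, dictionary: MRFDictionary):
    """Vectorized matcher core: signals (P, N) -> per-row best entry."""
    norms = np.linalg.norm(signals, axis=1)
    valid = norms > signals.shape[1] * np.finfo(float).eps
    scores = np.abs(signals @ dictionary.atoms.conj().T)  # (P, M)
    best = np.argmax(scores, axis=1)  # first max -> lowest atom index on ties
    coeff = scores[np.arange(len(best)), best]
    coeff_norm = np.where(valid, coeff / np.where(norms == 0, 1.0, norms), 0.0)
    return best, coeff_norm, coeff, valid


def match(signal, dictionary: MRFDictionary) -> MatchResult:
    """Match one signal evolution against the dictionary.

    The winning atom maximizes the magnitude inner product with the
    unit-normalized signal; ties break toward the lowest atom index (atoms
    are ordered by T1 then T2 ascending).  A zero-norm signal is flagged as
    background rather than raising.
    """
    s = np.asarray(signal, dtype=complex).ravel()
    if s.size != dictionary.atoms.shape[1]:
        raise InputDomainError(
            f"signal length {s.size} != atom length {dictionary.atoms.shape[1]}")
    best, coeff_norm, coeff, valid = _match_block(s[None, :], dictionary)
    if not valid[0]:
        return MatchResult(T1=0.0, T2=0.0, match_coefficient=0.0, scale=0.0, valid=False)
    t1, t2 = dictionary.lookup[best[0]]
    return MatchResult(T1=float(t1), T2=float(t2),
                       match_coefficient=float(min(coeff_norm[0], 1.0)),
                       scale=float(coeff[0]), valid=True)


def match_map(series, dictionary: MRFDictionary, mask=None,
              block_size: int = 4096):
    """Pixelwise dictionary matching of a (rows, cols, N) signal series.

    Returns a dict of 2-D float maps: ``t1``, ``t2``, ``match`` (matching
    coefficient), ``scale``, and a boolean ``valid`` map.  Background pixels
    (outside ``mask``, or with zero-norm signal) carry 0 in every map and
    False in ``valid``.
    """
    series = np.asarray(series)
    if series.ndim != 3:
        raise InputDomainError("series must be (rows, cols, timepoints)")
    rows, cols, n = series.shape
    if n != dictionary.atoms.shape[1]:
        raise InputDomainError("series timepoints != dictionary atom length")
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (rows, cols):
            raise InputDomainError("mask shape must match series spatial dims")

    t1_map = np.zeros((rows, cols))
    t2_map = np.zeros((rows, cols))
    coeff_map = np.zeros((rows, cols))
    scale_map = np.zeros((rows, cols))
    valid_map = np.zeros((rows, cols), dtype=bool)

    flat_idx = np.flatnonzero(mask.ravel())
    flat_series = series.reshape(-1, n)
    for start in range(0, flat_idx.size, block_size):
        idx = flat_idx[start:start + block_size]
        best, coeff_norm, coeff, valid = _match_block(
            flat_series[idx].astype(complex, copy=False), dictionary)
        r, c = np.unravel_index(idx, (rows, cols))
        t1_map[r, c] = np.where(valid, dictionary.lookup[best, 0], 0.0)
        t2_map[r, c] = np.where(valid, dictionary.lookup[best, 1], 0.0)
        coeff_map[r, c] = np.minimum(coeff_norm, 1.0)
        scale_map[r, c] = np.where(valid, coeff, 0.0)
        valid_map[r, c] = valid
    return {"t1": t1_map, "t2": t2_map, "match": coeff_map,
            "scale": scale_map, "valid": valid_map}
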