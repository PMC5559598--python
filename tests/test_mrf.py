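"""MRF engine: schedule generation, grid expansion, EPG simulation,
dictionary building and inner-product matching."""

import numpy as np
import pytest

from dcmrf import InputDomainError
from dcmrf.mrf import (DictionaryGrid, MRFDictionary, build_dictionary,
                       expand_grid, make_default_schedule, match, match_map,
                       simulate_fisp, simulate_fisp_batch)

from oracles import bloch_fisp


class TestSchedule:
    def test_default_shape_and_bounds(self):
        sched = make_default_schedule(n=3000, baseline_tr=12.0, seed=1)
        assert len(sched) == 3000
        assert np.all(sched.flip_angles_deg >= 0)
        assert np.all(sched.flip_angles_deg <= 75.0)
        assert np.all(sched.repetition_times_ms >= 12.0)
        assert np.all(sched.repetition_times_ms <= 15.0)
        assert sched.repetition_times_ms.mean() >= 12.0
        # full train plays out in tens of seconds
        assert 30_000 < sched.duration_ms < 60_000

    def test_deterministic_given_seed(self):
        a = make_default_schedule(n=500, seed=3)
        b = make_default_schedule(n=500, seed=3)
        assert np.array_equal(a.flip_angles_deg, b.flip_angles_deg)
        assert np.array_equal(a.repetition_times_ms, b.repetition_times_ms)
        assert a.fingerprint() == b.fingerprint()
        assert a.fingerprint() != make_default_schedule(n=500, seed=4).fingerprint()

    def test_length_one_schedule_valid(self):
        assert len(make_default_schedule(n=1, seed=0)) == 1

    def test_te_must_be_below_min_tr(self):
        from dcmrf.mrf import MRFSchedule
        with pytest.raises(InputDomainError):
            MRFSchedule(flip_angles_deg=np.array([30.0]),
                        repetition_times_ms=np.array([5.0]), echo_time_ms=6.0)


class TestGrid:
    def test_default_axis_counts(self):
        """Segment unions: 105 distinct T1 and 100 distinct T2 values.

        Brute-force enumeration of the piecewise lists, counting boundary
        values shared by consecutive segments once.
        """
        def brute(segments):
            values = set()
            for start, stop, step in segments:
                v = start
                while v <= stop + 1e-9:
                    values.add(round(v, 6))
                    v += step
            return values

        grid = DictionaryGrid.default(t2_le_t1=False)
        t1_brute = brute(grid.t1_segments)
        t2_brute = brute(grid.t2_segments)
        assert len(t1_brute) == 105
        assert len(t2_brute) == 100
        pairs = expand_grid(grid)
        assert len(pairs) == 105 * 100
        assert set(np.unique(pairs[:, 0])) == t1_brute
        assert set(np.unique(pairs[:, 1])) == t2_brute

    def test_single_degenerate_segment(self):
        grid = DictionaryGrid(((10, 10, 10),), ((10, 10, 10),), t2_le_t1=True)
        assert expand_grid(grid).tolist() == [[10.0, 10.0]]

    def test_t2_le_t1_filter(self):
        pairs = expand_grid(DictionaryGrid.default())
        assert np.all(pairs[:, 1] <= pairs[:, 0])

    def test_pairs_sorted_by_t1_then_t2(self):
        pairs = expand_grid(DictionaryGrid.coarse())
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        assert np.array_equal(order, np.arange(len(pairs)))

    def test_invalid_segments_rejected(self):
        with pytest.raises(InputDomainError):
            DictionaryGrid(((100, 50, 10),), ((2, 100, 2),))
        with pytest.raises(InputDomainError):
            DictionaryGrid(((10, 100, 0),), ((2, 100, 2),))


class TestEPG:
    def test_zero_flip_angles_give_zero_signal(self):
        sched = make_default_schedule(n=50, seed=0)
        from dcmrf.mrf import MRFSchedule
        silent = MRFSchedule(flip_angles_deg=np.zeros(50),
                             repetition_times_ms=sched.repetition_times_ms)
        assert np.allclose(simulate_fisp(1000.0, 100.0, silent), 0.0)

    def test_vanishing_t2_kills_signal(self):
        sched = make_default_schedule(n=50, seed=0)
        s = simulate_fisp(1000.0, 1e-3, sched)
        assert np.max(np.abs(s)) < 1e-10

    def test_epg_matches_isochromat_bloch(self):
        """20 random (T1, T2, schedule) triples, N <= 200: < 1% relative RMS
        against the brute-force Bloch oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(30, 201))
            sched = make_default_schedule(n=n, seed=int(rng.integers(0, 1000)))
            t1 = float(rng.uniform(100, 3000))
            t2 = float(rng.uniform(20, min(t1, 1500)))
            epg = simulate_fisp(t1, t2, sched, n_states=n + 1)
            bloch = bloch_fisp(t1, t2, sched, n_spins=512)
            rel_rms = (np.sqrt(np.mean(np.abs(epg - bloch) ** 2))
                       / np.sqrt(np.mean(np.abs(bloch) ** 2)))
            assert rel_rms < 0.01

    def test_truncation_default_adequate(self):
        """The default truncation order changes long-T2 signals by < 1%."""
        sched = make_default_schedule(n=600, seed=5)
        loose = simulate_fisp(4500.0, 3000.0, sched)  # default n_states
        exact = simulate_fisp(4500.0, 3000.0, sched, n_states=601)
        rel = np.linalg.norm(loose - exact) / np.linalg.norm(exact)
        assert rel < 0.01

    def test_batch_equals_scalar_path(self):
        sched = make_default_schedule(n=80, seed=8)
        batch = simulate_fisp_batch([300.0, 1000.0], [50.0, 200.0], sched)
        assert np.array_equal(batch[0], simulate_fisp(300.0, 50.0, sched))
        assert np.array_equal(batch[1], simulate_fisp(1000.0, 200.0, sched))

    def test_invalid_times_rejected(self):
        sched = make_default_schedule(n=10, seed=0)
        with pytest.raises(InputDomainError):
            simulate_fisp(-5.0, 100.0, sched)
        with pytest.raises(InputDomainError):
            simulate_fisp(np.inf, 100.0, sched)


class TestDictionary:
    def test_atoms_unit_norm_and_aligned_with_lookup(self, coarse_dictionary):
        norms = np.linalg.norm(coarse_dictionary.atoms, axis=1)
        np.testing.assert_allclose(norms, 1.0, rtol=1e-12)
        assert len(coarse_dictionary) == len(coarse_dictionary.lookup)

    def test_two_pair_dictionary(self, short_schedule):
        grid = DictionaryGrid(((500, 1000, 500),), ((100, 100, 100),))
        d = build_dictionary(grid, short_schedule)
        assert len(d) == 2
        np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=1), 1.0)

    def test_rebuild_bit_identical(self, short_schedule):
        grid = DictionaryGrid(((200, 600, 200),), ((50, 150, 50),))
        a = build_dictionary(grid, short_schedule)
        b = build_dictionary(grid, short_schedule)
        assert np.array_equal(a.atoms, b.atoms)

    def test_save_load_round_trip(self, coarse_dictionary, tmp_path):
        path = tmp_path / "dict.h5"
        coarse_dictionary.save(path)
        loaded = MRFDictionary.load(path)
        assert np.array_equal(loaded.atoms, coarse_dictionary.atoms)
        assert np.array_equal(loaded.lookup, coarse_dictionary.lookup)
        assert loaded.schedule_fingerprint == coarse_dictionary.schedule_fingerprint
        assert loaded.grid == coarse_dictionary.grid


class TestMatch:
    def test_every_atom_matches_itself(self, coarse_dictionary):
        scores = np.abs(coarse_dictionary.atoms @ coarse_dictionary.atoms.conj().T)
        best = np.argmax(scores, axis=1)
        assert np.array_equal(best, np.arange(len(coarse_dictionary)))

    def test_self_match_returns_own_entry(self, coarse_dictionary):
        idx = 123
        result = match(coarse_dictionary.atoms[idx], coarse_dictionary)
        t1, t2 = coarse_dictionary.lookup[idx]
        assert (result.T1, result.T2) == (t1, t2)
        assert result.match_coefficient == pytest.approx(1.0, abs=1e-12)

    def test_scale_and_phase_invariance(self, coarse_dictionary):
        idx = 200
        atom = coarse_dictionary.atoms[idx]
        base = match(atom, coarse_dictionary)
        scaled = match(2.5 * atom, coarse_dictionary)
        rotated = match(atom * np.exp(1j * 1.1), coarse_dictionary)
        assert (scaled.T1, scaled.T2) == (base.T1, base.T2)
        assert scaled.match_coefficient == pytest.approx(base.match_coefficient)
        assert scaled.scale == pytest.approx(2.5 * base.scale)
        assert (rotated.T1, rotated.T2) == (base.T1, base.T2)
        assert rotated.scale == pytest.approx(base.scale)

    def test_zero_signal_flagged_background(self, coarse_dictionary):
        result = match(np.zeros(coarse_dictionary.atoms.shape[1]), coarse_dictionary)
        assert not result.valid
        assert (result.T1, result.T2, result.scale) == (0.0, 0.0, 0.0)

    def test_noise_robustness_snr30(self, coarse_dictionary):
        """Atom + complex noise at SNR 30: correct (T1,T2) in >= 99% of
        1000 trials."""
        rng = np.random.default_rng(77)
        n_trials = 1000
        idx = rng.integers(0, len(coarse_dictionary), n_trials)
        atoms = coarse_dictionary.atoms
        peak = np.max(np.abs(atoms), axis=1)[idx]
        sd = (peak / 30.0 / np.sqrt(2.0))[:, None]
        noisy = atoms[idx] + sd * (rng.normal(size=(n_trials, atoms.shape[1]))
                                   + 1j * rng.normal(size=(n_trials, atoms.shape[1])))
        scores = np.abs(noisy @ atoms.conj().T)
        best = np.argmax(scores, axis=1)
        assert np.mean(best == idx) >= 0.99

    def test_off_grid_quantization_bound(self, coarse_dictionary, short_schedule):
        """Noise-free off-grid signals match within one grid step per axis
        for >= 95% of 200 random draws inside the grid hull."""
        grid = coarse_dictionary.grid
        t1_values = np.unique(coarse_dictionary.lookup[:, 0])
        t2_values = np.unique(coarse_dictionary.lookup[:, 1])
        rng = np.random.default_rng(31)
        t1 = rng.uniform(t1_values[0], t1_values[-1], 200)
        t2 = np.minimum(rng.uniform(t2_values[0], t2_values[-1], 200), t1)
        signals = simulate_fisp_batch(t1, t2, short_schedule, n_states=60)

        def local_step(values, x):
            i = np.searchsorted(values, x)
            lo = values[max(i - 1, 0)]
            hi = values[min(i, len(values) - 1)]
            return max(hi - lo, values[1] - values[0])

        ok = 0
        for k in range(200):
            res = match(signals[k], coarse_dictionary)
            if (abs(res.T1 - t1[k]) <= local_step(t1_values, t1[k])
                    and abs(res.T2 - t2[k]) <= local_step(t2_values, t2[k])):
                ok += 1
        assert ok / 200 >= 0.95

    def test_length_mismatch_rejected(self, coarse_dictionary):
        with pytest.raises(InputDomainError):
            match(np.ones(3), coarse_dictionary)


class TestMatchMap:
    def test_pattern_of_atoms_reproduced_exactly(self, coarse_dictionary):
        rng = np.random.default_rng(1)
        n = coarse_dictionary.atoms.shape[1]
        idx = rng.integers(0, len(coarse_dictionary), size=(6, 7))
        series = coarse_dictionary.atoms[idx]
        maps = match_map(series, coarse_dictionary)
        np.testing.assert_array_equal(maps["t1"], coarse_dictionary.lookup[idx, 0])
        np.testing.assert_array_equal(maps["t2"], coarse_dictionary.lookup[idx, 1])
        assert maps["valid"].all()

    def test_all_zero_series_is_background(self, coarse_dictionary):
        n = coarse_dictionary.atoms.shape[1]
        maps = match_map(np.zeros((4, 5, n)), coarse_dictionary)
        assert not maps["valid"].any()
        assert np.all(maps["t1"] == 0) and np.all(maps["t2"] == 0)

    def test_mask_and_dimension_checks(self, coarse_dictionary):
        n = coarse_dictionary.atoms.shape[1]
        series = np.ones((3, 3, n), dtype=complex)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        maps = match_map(series, coarse_dictionary, mask=mask)
        assert maps["valid"].sum() == 1
        with pytest.raises(InputDomainError):
            match_map(series, coarse_dictionary, mask=np.ones((2, 2), bool))
        with pytest.raises(InputDomainError):
            match_map(series[..., :5], coarse_dictionary)
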