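"""Dictionary construction, dot-product matching, and SVD compression."""

import numpy as np
import pytest

from myot2.dictionary_fit import (
    ParamGrid,
    build_dictionary,
    build_grid,
    compress_svd,
    load_dictionary,
    match,
    match_compressed,
    save_dictionary,
)
from myot2.epg_core import TissueParams, mese_two_component


@pytest.fixture(scope="module")
def toy_dict(seq_profile):
    """Coarse 10 x 10 x 3 muscle grid: well-separated atoms."""
    grid = build_grid(
        "muscle",
        t2f=151.0,
        ff=(0.0, 0.9, 0.1),
        t2w=(15.0, 69.0, 6.0),
        b1=(0.6, 1.2, 0.3),
    )
    return build_dictionary(grid, seq_profile)


class TestGrid:
    def test_fat_grid_axis_counts(self):
        g = build_grid("fat")
        assert g.shape == (801, 201, 33)
        assert g.fixed == {"ff": 0.9}

    def test_muscle_grid_axis_counts(self):
        g = build_grid("muscle", t2f=151.0)
        names = dict(zip(g.axis_names, g.shape))
        assert names["t2w"] == 351
        assert names["b1"] == 33
        assert g.fixed == {"t2f": 151.0}

    def test_step_equal_to_range_gives_two_points(self):
        g = build_grid("muscle", t2f=151.0, t2w=(10.0, 80.0, 70.0))
        np.testing.assert_allclose(g.axis_values("t2w"), [10.0, 80.0])

    def test_invalid_overrides_rejected(self):
        with pytest.raises(ValueError):
            build_grid("muscle", t2f=151.0, t2w=(80.0, 10.0, 1.0))
        with pytest.raises(ValueError):
            build_grid("fat", b1=(0.4, 1.2, -0.1))
        with pytest.raises(ValueError):
            build_grid("muscle", t2f=500.0)
        with pytest.raises(ValueError):
            build_grid("spleen")


class TestBuild:
    def test_toy_grid_atom_count_and_norms(self, seq_profile):
        grid = ParamGrid(
            axes=(("ff", 0.0, 0.5, 0.5), ("t2w", 20.0, 40.0, 20.0), ("b1", 0.8, 1.0, 0.2)),
            fixed={"t2f": 151.0},
        )
        d = build_dictionary(grid, seq_profile)
        assert d.n_atoms == 8
        np.testing.assert_allclose(np.linalg.norm(d.atoms, axis=1), 1.0, atol=1e-9)

    def test_rebuild_is_bit_identical(self, seq_profile, toy_dict):
        again = build_dictionary(toy_dict.grid, seq_profile)
        assert np.array_equal(again.atoms, toy_dict.atoms)

    def test_cpmg_atom_closed_form(self, seq_ideal):
        grid = ParamGrid(
            axes=(("ff", 0.0, 0.0, 1.0), ("t2w", 50.0, 50.0, 1.0), ("b1", 1.0, 1.0, 1.0)),
            fixed={"t2f": 151.0},
        )
        d = build_dictionary(grid, seq_ideal)
        expected = np.exp(-np.arange(1, 18) * 7.5 / 50.0)
        np.testing.assert_allclose(d.atoms[0], expected / np.linalg.norm(expected), rtol=1e-9)

    def test_atoms_match_direct_two_component_simulation(self, seq_profile, toy_dict):
        pts = toy_dict.grid.points()
        names = toy_dict.grid.axis_names
        for i in (0, 57, 299):
            kw = dict(zip(names, pts[i]))
            sig = mese_two_component(
                TissueParams(t2f_ms=151.0, t2w_ms=kw["t2w"], ff=kw["ff"], b1=kw["b1"]),
                seq_profile,
            )
            np.testing.assert_allclose(toy_dict.atoms[i], sig / np.linalg.norm(sig), rtol=1e-12)

    def test_memory_guard(self, seq_profile, toy_dict):
        with pytest.raises(MemoryError):
            build_dictionary(toy_dict.grid, seq_profile, atom_limit=10)


class TestMatch:
    def test_self_retrieval_exact(self, toy_dict):
        res = match(toy_dict.atoms, toy_dict)
        pts = toy_dict.grid.points()
        for i, nm in enumerate(toy_dict.grid.axis_names):
            np.testing.assert_array_equal(res[nm], pts[:, i])
        assert np.all(res["score"] >= 1.0 - 1e-9)

    def test_scaling_invariance(self, toy_dict):
        a = match(toy_dict.atoms[17], toy_dict)
        b = match(5.3 * toy_dict.atoms[17], toy_dict)
        for nm in toy_dict.grid.axis_names:
            assert a[nm][0] == b[nm][0]

    def test_off_grid_signal_snaps_to_nearest(self, seq_profile):
        grid = build_grid("muscle", t2f=151.0, ff=(0.2, 0.2, 1.0), b1=(1.0, 1.0, 1.0))
        d = build_dictionary(grid, seq_profile)
        sig = mese_two_component(
            TissueParams(t2f_ms=151.0, t2w_ms=50.07, ff=0.2, b1=1.0), seq_profile
        )
        res = match(sig, d)
        assert res["t2w"][0] == pytest.approx(50.0)

    def test_zero_signal_flagged(self, toy_dict):
        res = match(np.zeros(17), toy_dict)
        assert np.isnan(res["t2w"][0]) and np.isnan(res["score"][0])

    def test_wrong_length_rejected(self, toy_dict):
        with pytest.raises(ValueError):
            match(np.ones(5), toy_dict)


class TestCompression:
    def test_lossless_at_full_rank(self, toy_dict):
        c = compress_svd(toy_dict, toy_dict.etl)
        rng = np.random.default_rng(1)
        sig = np.abs(rng.standard_normal((1000, 17)))
        full = match(sig, toy_dict)
        comp = match_compressed(sig, c)
        for nm in toy_dict.grid.axis_names:
            np.testing.assert_array_equal(full[nm], comp[nm])

    def test_rank3_self_match_on_coarse_grid(self, seq_profile):
        # 3 components separate a coarse (FF, T2w) manifold perfectly;
        # adding a B1 axis needs higher rank for exact self-retrieval
        grid = build_grid(
            "muscle", t2f=151.0, ff=(0.0, 0.9, 0.1), t2w=(15.0, 60.0, 5.0),
            b1=(1.0, 1.0, 1.0),
        )
        d = build_dictionary(grid, seq_profile)
        c = compress_svd(d, 3)
        res = match_compressed(d.atoms, c)
        pts = d.grid.points()
        for i, nm in enumerate(d.grid.axis_names):
            np.testing.assert_array_equal(res[nm], pts[:, i])

    def test_variance_ratios_monotone_and_normalized(self, toy_dict):
        c = compress_svd(toy_dict, 3)
        evr = c.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.sum(evr) == pytest.approx(1.0)
        assert np.all(np.diff(c.explained_variance_ratio_centered) <= 1e-12)

    def test_rank1_synthetic_dictionary(self, toy_dict):
        atoms = np.tile(toy_dict.atoms[0], (5, 1))
        from dataclasses import replace

        rank1 = replace(toy_dict, atoms=atoms)
        c = compress_svd(rank1, 1)
        assert c.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_k_out_of_range(self, toy_dict):
        with pytest.raises(ValueError):
            compress_svd(toy_dict, 0)
        with pytest.raises(ValueError):
            compress_svd(toy_dict, 18)


def test_hdf5_round_trip(tmp_path, toy_dict):
    path = tmp_path / "dict.h5"
    save_dictionary(toy_dict, path)
    back = load_dictionary(path)
    assert np.array_equal(back.atoms, toy_dict.atoms)
    assert back.seq_hash == toy_dict.seq_hash
    assert back.grid.axes == toy_dict.grid.axes
    assert back.grid.fixed == toy_dict.grid.fixed
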