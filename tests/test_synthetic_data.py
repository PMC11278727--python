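import json
import math
import os

import numpy as np
import pytest

from micromr.errors import DomainError
from micromr.estimate import estimate_exposure, ivw_pool, wald_pvalue, wald_ratio
from micromr.sumstats_io import read_ld, read_sumstats
from micromr.synthetic_data import SimTruth, make_ld, make_panel, simulate

from conftest import harmonized_from_sim


class TestMakeLD:
    def test_rho_zero_identity_only(self):
        ref = make_ld(blocks=2, block_size=3, rho=0.0)
        assert list(ref.pairs()) == []
        ids = list(ref.positions)
        assert ref.r(ids[0], ids[0]) == 1.0

    def test_ar1_power(self):
        ref = make_ld(blocks=1, block_size=3, rho=0.5)
        ids = list(ref.positions)
        assert ref.r(ids[0], ids[2]) == pytest.approx(0.25)
        assert ref.r(ids[0], ids[1]) == pytest.approx(0.5)

    def test_cross_block_zero(self):
        ref = make_ld(blocks=2, block_size=2, rho=0.9)
        ids = list(ref.positions)
        assert ref.r(ids[0], ids[2]) == 0.0

    def test_blocks_on_distinct_chromosomes(self):
        ref = make_ld(blocks=3, block_size=2, rho=0.5)
        chroms = {chrom for chrom, _ in ref.positions.values()}
        assert chroms == {"1", "2", "3"}

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        ref = make_ld(
            blocks=int(rng.integers(1, 4)),
            block_size=int(rng.integers(1, 6)),
            rho=float(rng.uniform(-0.95, 0.95)),
        )
        ids = list(ref.positions)
        for a in ids:
            for b in ids:
                assert abs(ref.r(a, b)) <= 1.0
                assert ref.r(a, b) == ref.r(b, a)
            assert ref.r(a, a) == 1.0

    def test_rho_out_of_range(self):
        with pytest.raises(DomainError):
            make_ld(1, 2, rho=1.0)


def _truth(**kwargs):
    defaults = dict(
        theta_true=0.5, gamma=10 / math.sqrt(1800), blocks=3, block_size=1,
        rho=0.0, n_x=1800, n_y=11_600, n_case_frac=0.41, seed=123,
    )
    defaults.update(kwargs)
    return SimTruth(**defaults)


class TestSimTruthValidation:
    def test_small_n_rejected(self):
        with pytest.raises(DomainError):
            _truth(n_x=50)

    def test_bad_case_frac(self):
        with pytest.raises(DomainError):
            _truth(n_case_frac=1.0)

    def test_gamma_broadcast(self):
        t = _truth(blocks=2, block_size=3, gamma=0.1)
        assert len(t.gamma) == 6


class TestSimulateFast:
    def test_determinism(self):
        a = simulate(_truth())
        b = simulate(_truth())
        ra = list(a.exposure_sumstats.records.values())
        rb = list(b.exposure_sumstats.records.values())
        assert ra == rb
        assert list(a.outcome_sumstats.records.values()) == list(
            b.outcome_sumstats.records.values()
        )

    def test_different_seed_differs(self):
        a = simulate(_truth(seed=1))
        b = simulate(_truth(seed=2))
        assert list(a.exposure_sumstats.records.values()) != list(
            b.exposure_sumstats.records.values()
        )

    def test_global_null_centers_outcome_at_zero(self):
        # no genetic effects at all: outcome betas are pure noise
        reps = [
            simulate(_truth(theta_true=0.7, gamma=0.0, seed=s)) for s in range(100)
        ]
        betas = np.array(
            [[r.beta for r in s.outcome_sumstats.records.values()] for s in reps]
        )
        se = 1 / math.sqrt(11_600 * 0.41 * 0.59)
        assert abs(betas.mean()) < 3 * se / math.sqrt(betas.size)

    def test_strong_instruments_have_genomewide_p(self):
        sim = simulate(_truth())
        for rec in sim.exposure_sumstats.records.values():
            assert rec.pvalue < 1e-8

    def test_outcome_is_binary_with_counts(self):
        sim = simulate(_truth())
        rec = next(iter(sim.outcome_sumstats.records.values()))
        assert rec.n_case == pytest.approx(round(11_600 * 0.41))
        assert rec.n_control == pytest.approx(11_600 - round(11_600 * 0.41))

    def test_reverse_mode_swaps_roles(self):
        fwd = simulate(_truth(seed=9))
        rev = simulate(_truth(seed=9, reverse=True, theta_true=0.3, gamma=0.3))
        # reverse: exposure effects are attenuated copies of direct outcome effects
        bx = np.array([r.beta for r in rev.exposure_sumstats.records.values()])
        by = np.array([r.beta for r in rev.outcome_sumstats.records.values()])
        assert np.mean(np.abs(bx)) < np.mean(np.abs(by)) * 0.3 / 0.1  # sanity scale
        assert fwd.truth.reverse is False


class TestGeneratedFilesValidate:
    def test_roundtrip_zero_rejections(self, tmp_path):
        from micromr.sumstats_io import write_ld, write_sumstats

        sim = simulate(_truth())
        write_sumstats(sim.exposure_sumstats, tmp_path / "exp.tsv")
        write_sumstats(sim.outcome_sumstats, tmp_path / "out.tsv")
        write_ld(sim.ld, tmp_path / "ld")
        exp = read_sumstats(tmp_path / "exp.tsv", "quantitative")
        out = read_sumstats(tmp_path / "out.tsv", "binary")
        ld = read_ld(tmp_path / "ld")
        assert exp.n_rejected == 0
        assert out.n_rejected == 0
        assert set(ld.positions) == set(sim.ld.positions)


class TestFastVsIndividualAgreement:
    def test_exposure_effect_distribution(self):
        # small fixed truth; agreement of the mean estimated effect within 3 MC SEs
        truth_kwargs = dict(
            theta_true=0.4, gamma=0.15, blocks=3, block_size=1, rho=0.0,
            n_x=1500, n_y=2500, n_case_frac=0.4,
        )
        n_rep = 30
        fast = np.array(
            [
                [r.beta for r in simulate(_truth(**truth_kwargs, seed=s)).exposure_sumstats.records.values()]
                for s in range(n_rep)
            ]
        )
        slow = np.array(
            [
                [
                    r.beta
                    for r in simulate(
                        _truth(**truth_kwargs, seed=1000 + s), mode="individual"
                    ).exposure_sumstats.records.values()
                ]
                for s in range(n_rep)
            ]
        )
        mc_se = math.sqrt(2.0 / (n_rep * 1500))  # ~ sqrt(2) * se_x / sqrt(n_rep)
        for j in range(3):
            assert abs(fast[:, j].mean() - slow[:, j].mean()) < 3 * mc_se
        # sampling spread agrees with the nominal 1/sqrt(n_x) within broad bounds
        assert np.allclose(slow.std(axis=0), 1 / math.sqrt(1500), rtol=0.6)

    def test_individual_outcome_recovers_theta(self):
        # per-variant logistic effects should imply theta near truth
        thetas = []
        for s in range(10):
            sim = simulate(
                _truth(theta_true=0.5, gamma=0.25, n_x=1500, n_y=3000, seed=s),
                mode="individual",
            )
            h = harmonized_from_sim(sim)
            res = estimate_exposure(h, "sim")
            thetas.append(res.theta)
        assert np.mean(thetas) == pytest.approx(0.5, abs=0.15)

    def test_individual_mode_rejects_ld(self):
        with pytest.raises(DomainError):
            simulate(_truth(rho=0.5, block_size=2), mode="individual")

    def test_unknown_mode(self):
        with pytest.raises(DomainError):
            simulate(_truth(), mode="magic")


class TestConfoundingAndPleiotropy:
    def test_confounding_only_keeps_nominal_type1(self):
        # instruments independent of the confounder: IV premise -> ~5% rejections
        n_rep = 150
        rejections = 0
        for s in range(n_rep):
            sim = simulate(
                _truth(
                    theta_true=0.0, gamma=0.3, n_x=800, n_y=1200,
                    confounder_effect_x=0.4, confounder_effect_y=0.4, seed=s,
                ),
                mode="individual",
            )
            h = harmonized_from_sim(sim)
            res = estimate_exposure(h, "sim")
            rejections += res.pvalue < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / n_rep)

    def test_pleiotropy_inflates_rejections(self):
        n_rep = 300
        rejections = 0
        for s in range(n_rep):
            sim = simulate(
                _truth(theta_true=0.0, phi=0.02, seed=10_000 + s)
            )
            h = harmonized_from_sim(sim)
            res = estimate_exposure(h, "sim")
            rejections += res.pvalue < 0.05
        assert rejections / n_rep > 0.15  # far above the nominal 5%


class TestMakePanel:
    def test_single_taxon_files(self, tmp_path):
        info = make_panel(1, [0.5], tmp_path, seed=3)
        assert os.path.exists(info["outcome_path"])
        assert os.path.exists(info["exposure_paths"][0])
        assert os.path.exists(os.path.join(info["ld_dir"], "ld.tsv"))
        assert os.path.exists(tmp_path / "truth.json")

    def test_same_seed_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_panel(3, [0.0, 0.5, -0.5], a, seed=11)
        make_panel(3, [0.0, 0.5, -0.5], b, seed=11)
        for name in sorted(os.listdir(a)):
            pa, pb = a / name, b / name
            if pa.is_dir():
                for sub in sorted(os.listdir(pa)):
                    assert (pa / sub).read_bytes() == (pb / sub).read_bytes()
            else:
                assert pa.read_bytes() == pb.read_bytes()

    def test_panel_files_validate_cleanly(self, tmp_path):
        info = make_panel(2, [0.5, 0.0], tmp_path, seed=4)
        out = read_sumstats(info["outcome_path"], "binary")
        assert out.n_rejected == 0
        for p in info["exposure_paths"]:
            assert read_sumstats(p, "quantitative").n_rejected == 0
        read_ld(info["ld_dir"])

    def test_truth_json_records_effects(self, tmp_path):
        info = make_panel(2, [0.25, -0.75], tmp_path, seed=5)
        with open(tmp_path / "truth.json") as fh:
            truth = json.load(fh)
        effects = sorted(t["theta_true"] for t in truth.values())
        assert effects == [-0.75, 0.25]
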