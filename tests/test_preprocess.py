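import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methburden import preprocess as pp
from methburden import synthdata as sd


def toy_matrices(n_probes=10, n_samples=20, seed=0):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:03d}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(n_samples)]
    betas = pd.DataFrame(rng.uniform(0.1, 0.9, (n_probes, n_samples)),
                         index=probes, columns=samples)
    ann = pd.DataFrame(dict(
        chrom=["1"] * n_probes, pos=np.arange(n_probes) + 1,
        design_type="II", gene="", feature="IGR",
        non_cpg=False, snp_related=False, multi_map=False,
        low_quality=False), index=pd.Index(probes, name="probe_id"))
    det = pd.DataFrame(np.full((n_probes, n_samples), 1e-4),
                       index=probes, columns=samples)
    beads = pd.DataFrame(np.full((n_probes, n_samples), 10),
                         index=probes, columns=samples)
    return betas, ann, det, beads


class TestFilterProbes:
    def test_flagged_probe_removed_and_counted(self):
        betas, ann, det, beads = toy_matrices()
        ann.loc["cg003", "snp_related"] = True
        out, rep = pp.filter_probes(betas, ann, det, beads)
        assert out.shape[0] == 9
        assert "cg003" not in out.index
        assert rep.removed_per_criterion["snp_related"] == 1

    def test_detection_p_sample_fraction_rule(self):
        betas, ann, det, beads = toy_matrices(n_samples=100)
        det.loc["cg001", det.columns[:6]] = 0.02   # 6% of samples fail
        det.loc["cg002", det.columns[:5]] = 0.02   # exactly 5%: retained
        out, rep = pp.filter_probes(betas, ann, det, beads)
        assert "cg001" not in out.index
        assert "cg002" in out.index
        assert rep.removed_per_criterion["detection_p"] == 1

    def test_clean_input_is_identity_and_idempotent(self):
        betas, ann, det, beads = toy_matrices()
        out, rep = pp.filter_probes(betas, ann, det, beads)
        assert out.equals(betas)
        out2, _ = pp.filter_probes(out, ann.loc[out.index],
                                   det.loc[out.index], beads.loc[out.index])
        assert out2.equals(out)

    def test_sex_chromosome_probes_retained(self):
        betas, ann, det, beads = toy_matrices()
        ann.loc["cg000", "chrom"] = "X"
        ann.loc["cg001", "chrom"] = "Y"
        out, _ = pp.filter_probes(betas, ann, det, beads)
        assert {"cg000", "cg001"} <= set(out.index)

    def test_missing_companion_named_in_error(self):
        betas, ann, det, beads = toy_matrices()
        with pytest.raises(ValueError, match="detection_p"):
            pp.filter_probes(betas, ann, None, beads)
        with pytest.raises(ValueError, match="beadcount"):
            pp.filter_probes(betas, ann, det, None)


class TestDropBadSamples:
    def test_boundary_is_strict(self):
        betas, ann, det, beads = toy_matrices(n_probes=50)
        det.loc[det.index[:6], "s0"] = 0.5    # 12% of probes fail in s0
        det.loc[det.index[:5], "s1"] = 0.5    # exactly 10%: retained
        _, rep = pp.filter_probes(betas, ann, det, beads)
        out = pp.drop_bad_samples(betas, rep)
        assert "s0" not in out.columns
        assert "s1" in out.columns

    def test_all_clean_identity(self):
        betas, ann, det, beads = toy_matrices()
        _, rep = pp.filter_probes(betas, ann, det, beads)
        assert pp.drop_bad_samples(betas, rep).equals(betas)


class TestPredictSex:
    def test_synthetic_cohort_recovered_and_swap_flagged(self, default_cohort):
        coh = default_cohort
        swapped = coh.samples["sex"].copy()
        victim = swapped.index[0]
        swapped.loc[victim] = "M" if swapped.loc[victim] == "F" else "F"
        feats, mismatches = pp.predict_sex(coh.betas, coh.annotation, swapped)
        assert mismatches == [victim]
        true_sex = coh.samples["sex"]
        assert (feats["predicted_sex"] == true_sex).all()

    def test_requires_sex_chromosome_probes(self):
        betas, ann, det, beads = toy_matrices()
        with pytest.raises(ValueError):
            pp.predict_sex(betas, ann)


class TestBMIQ:
    def test_ks_distance_strictly_decreases(self, default_cohort):
        """Synthetic type-II compression is a real bias: BMIQ must bring
        the type-II distribution closer to type-I in every sample."""
        coh = default_cohort
        sub = coh.betas.iloc[:, :5]
        norm = pp.bmiq_normalize(sub, coh.annotation)
        t1 = (coh.annotation["design_type"] == "I").to_numpy()
        t2 = (coh.annotation["design_type"] == "II").to_numpy()
        for j in range(sub.shape[1]):
            before = stats.ks_2samp(sub.to_numpy()[t1, j],
                                    sub.to_numpy()[t2, j]).statistic
            after = stats.ks_2samp(norm.to_numpy()[t1, j],
                                   norm.to_numpy()[t2, j]).statistic
            assert after < before

    def test_type1_probes_bit_identical(self, default_cohort):
        coh = default_cohort
        sub = coh.betas.iloc[:, :3]
        norm = pp.bmiq_normalize(sub, coh.annotation)
        t1 = (coh.annotation["design_type"] == "I").to_numpy()
        assert np.array_equal(sub.to_numpy()[t1], norm.to_numpy()[t1])

    def test_rank_order_preserved_within_sample(self, default_cohort):
        coh = default_cohort
        sub = coh.betas.iloc[:, :3]
        norm = pp.bmiq_normalize(sub, coh.annotation)
        t2 = (coh.annotation["design_type"] == "II").to_numpy()
        for j in range(sub.shape[1]):
            x = sub.to_numpy()[t2, j]
            y = norm.to_numpy()[t2, j]
            order = np.argsort(x, kind="mergesort")
            assert (np.diff(y[order]) >= -1e-9).all()

    def test_matched_distributions_near_identity(self):
        """When type-II already matches type-I there is no bias to
        correct: the transform stays close to the identity."""
        rng = np.random.default_rng(3)

        def draw(n):
            comp = rng.choice(3, size=n, p=[0.4, 0.2, 0.4])
            a = np.where(comp == 0, rng.beta(2, 12, n),
                         np.where(comp == 1, rng.beta(10, 10, n),
                                  rng.beta(12, 2, n)))
            return a

        n = 3000
        probes = [f"cg{i:05d}" for i in range(2 * n)]
        shared = draw(n)
        vals = np.concatenate([shared, shared])  # type-II == type-I
        betas = pd.DataFrame({"s0": vals}, index=probes)
        ann = pd.DataFrame(dict(
            chrom="1", pos=1, design_type=["I"] * n + ["II"] * n,
            gene="", feature="IGR"), index=pd.Index(probes))
        norm = pp.bmiq_normalize(betas, ann)
        change = np.abs(norm.to_numpy()[n:, 0] - vals[n:])
        assert change.max() < 0.02


class TestCellProportions:
    def _reference(self):
        rng = np.random.default_rng(5)
        probes = [f"cg{i:04d}" for i in range(120)]
        return pd.DataFrame({
            "neuron": rng.uniform(0.05, 0.95, 120),
            "non_neuron": rng.uniform(0.05, 0.95, 120),
        }, index=pd.Index(probes, name="probe_id"))

    def test_pure_profile_and_5050_mixture(self):
        ref = self._reference()
        betas = pd.DataFrame({
            "pure": ref["neuron"],
            "half": 0.5 * ref["neuron"] + 0.5 * ref["non_neuron"],
        })
        props = pp.estimate_cell_proportions(betas, ref)
        assert props.loc["pure", "neuron"] == pytest.approx(1.0, abs=0.01)
        assert props.loc["pure", "non_neuron"] == pytest.approx(0.0, abs=0.01)
        assert props.loc["half", "neuron"] == pytest.approx(0.5, abs=0.01)
        assert props.loc["half", "non_neuron"] == pytest.approx(0.5, abs=0.01)

    def test_synthetic_cohort_recovery(self, default_cohort):
        coh = default_cohort
        props = pp.estimate_cell_proportions(coh.betas, coh.cell_reference)
        r = np.corrcoef(props["neuron"], coh.samples["neuron_true"])[0, 1]
        assert r > 0.95

    def test_too_few_overlapping_probes(self):
        ref = self._reference().iloc[:30]
        betas = pd.DataFrame({"s": ref["neuron"]})
        with pytest.raises(ValueError, match="50"):
            pp.estimate_cell_proportions(betas, ref)


class TestCorrectBatch:
    def test_single_batch_identity(self):
        betas, ann, det, beads = toy_matrices()
        sheet = pd.DataFrame(dict(batch="0", diagnosis="control", sex="F"),
                             index=betas.columns)
        assert pp.correct_batch(betas, sheet).equals(betas)

    def test_planted_shift_removed(self):
        cfg = sd.CohortConfig(n_probes=1500, frac_fdmp=0, frac_mdmp=0,
                              frac_shared=0, frac_sdmp=0, batch_shift=0.05,
                              noise_sd=0.2, seed=7)
        coh = sd.generate_cohort(cfg)
        corrected = pp.correct_batch(coh.betas, coh.samples)

        def mean_batch_diff(m):
            g = m.T.groupby(coh.samples["batch"]).mean()
            return float((g.iloc[0] - g.iloc[1]).abs().mean())

        before = mean_batch_diff(coh.betas)
        after = mean_batch_diff(corrected)
        assert before > 0.04            # the planted 0.05 shift is there
        assert after < 0.005
        assert after < 0.1 * before     # >= 90% of the shift removed

    def test_protected_diagnosis_effect_preserved(self):
        cfg = sd.CohortConfig(n_probes=1500, frac_fdmp=0.05, frac_mdmp=0,
                              frac_shared=0, frac_sdmp=0, delta_female=0.10,
                              batch_shift=0.05, noise_sd=0.2, seed=8)
        coh = sd.generate_cohort(cfg)
        corrected = pp.correct_batch(coh.betas, coh.samples)
        f = (coh.samples["sex"] == "F").to_numpy()
        case = (coh.samples["diagnosis"] == "case").to_numpy()
        planted = (coh.truth["true_delta_female"] != 0).to_numpy()

        def effect(m):
            return (m.loc[planted, f & case].mean(axis=1)
                    - m.loc[planted, f & ~case].mean(axis=1)).to_numpy()

        e0, e1 = effect(coh.betas), effect(corrected)
        assert np.abs(e1 - e0).mean() < 0.1 * np.abs(e0).mean()

    def test_confounded_batch_rejected(self):
        betas, *_ = toy_matrices(n_samples=20)
        sheet = pd.DataFrame(dict(
            batch=["a"] * 10 + ["b"] * 10,
            diagnosis=["case"] * 10 + ["control"] * 10,
            sex="F"), index=betas.columns)
        with pytest.raises(ValueError, match="confounded"):
            pp.correct_batch(betas, sheet)


class TestSurrogateVariables:
    def test_null_matrix_selects_zero_components(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            noise = pd.DataFrame(
                1 / (1 + np.exp(-rng.normal(0, 0.5, (800, 40)))),
                index=[f"p{i}" for i in range(800)],
                columns=[f"s{i}" for i in range(40)])
            X = pd.DataFrame({"x": rng.integers(0, 2, 40)},
                             index=noise.columns)
            _, k = pp.estimate_svs(noise, X, seed=s)
            hits += (k == 0)
        assert hits >= 18

    def test_planted_latent_factor_recovered(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(0, 1, 60)
        M = rng.normal(0, 1, (1500, 60)) * 0.5
        affected = rng.random(1500) < 0.3
        M[affected] += np.outer(rng.normal(0, 0.8, affected.sum()), latent)
        betas = pd.DataFrame(1 / (1 + np.exp(-M)),
                             index=[f"p{i}" for i in range(1500)],
                             columns=[f"s{i}" for i in range(60)])
        X = pd.DataFrame({"x": rng.integers(0, 2, 60)}, index=betas.columns)
        svs, k = pp.estimate_svs(betas, X, seed=1)
        assert k >= 1
        assert abs(np.corrcoef(svs.iloc[:, 0], latent)[0, 1]) > 0.8

    def test_svs_zero_mean_and_orthogonal(self, default_cohort):
        coh = default_cohort
        X = pd.get_dummies(coh.samples[["diagnosis", "sex"]],
                           drop_first=True).astype(float)
        svs, k = pp.estimate_svs(coh.betas, X, seed=0)
        if k >= 1:
            assert np.abs(svs.mean(axis=0)).max() < 1e-8
        if k >= 2:
            gram = svs.T.to_numpy() @ svs.to_numpy()
            off = gram - np.diag(np.diag(gram))
            assert np.abs(off).max() < 1e-8

    def test_too_few_samples_rejected(self):
        betas, *_ = toy_matrices(n_probes=30, n_samples=4)
        X = pd.DataFrame(np.eye(4)[:, :3], index=betas.columns)
        with pytest.raises(ValueError):
            pp.estimate_svs(betas, X)
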