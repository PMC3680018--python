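import numpy as np
import pandas as pd
import pytest

from podscan.annotate import (BaselineContext, assign_abnormality_type,
                              assign_inheritance, build_baselines,
                              filter_parental_artifacts, local_baseline,
                              resolve_overlaps)
from podscan.sample_stats import SampleParams
from podscan.trio_data import Region, TrioDataset


def _dataset(n=2000, child_lrr=0.0, span=None, child_baf_fn=None,
             parent_lrr=("father", 0.0), child_gt=None, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "name": [f"s{i}" for i in range(n)],
        "chrom": ["1"] * n, "pos": np.arange(n) * 100 + 1,
    })
    for c in "fmc":
        df[f"{c}_gt"] = np.ones(n, np.int8)
        df[f"{c}_baf"] = np.clip(rng.normal(0.5, 0.03, n), 0, 1)
        df[f"{c}_lrr"] = rng.normal(0.0, 0.15, n)
    if span is not None:
        sl = slice(span[0], span[1] + 1)
        lrr = df["c_lrr"].to_numpy()
        lrr[sl] += child_lrr
        df["c_lrr"] = lrr
        member, delta = parent_lrr
        col = {"father": "f_lrr", "mother": "m_lrr"}[member]
        plrr = df[col].to_numpy()
        plrr[sl] += delta
        df[col] = plrr
        if child_baf_fn is not None:
            baf = df["c_baf"].to_numpy()
            baf[sl] = child_baf_fn(rng, span[1] - span[0] + 1)
            df["c_baf"] = baf
        if child_gt is not None:
            gt = df["c_gt"].to_numpy().copy()
            gt[sl] = child_gt
            df["c_gt"] = gt
    return TrioDataset(df, {"1q": (0, n)})


PARAMS = {m: SampleParams(member=m, het_mi1_rate=1e-4, error_rate=0.004)
          for m in ("father", "mother", "child")}


def _region(a, b, parent="father", detector="POD", n_inf=50):
    return Region(chrom="1", arm="1q", start_idx=a, end_idx=b,
                  detector=detector, parent=parent, n_informative=n_inf)


def _annotate(data, region):
    called = np.zeros(data.n_snps, bool)
    called[region.start_idx:region.end_idx + 1] = True
    base = local_baseline(data, "1q", called, PARAMS)
    return assign_abnormality_type(region, data, PARAMS, base), base


class TestTypeAssignment:
    def test_amplification(self):
        data = _dataset(child_lrr=0.24, span=(500, 900))
        r, _ = _annotate(data, _region(500, 900))
        assert r.abn_type == "AMP"
        assert r.med_lrr["child"] == pytest.approx(0.24, abs=0.05)

    def test_deletion_with_parent_flip(self):
        data = _dataset(child_lrr=-0.475, span=(500, 900))
        r, _ = _annotate(data, _region(500, 900, parent="mother"))
        assert r.abn_type == "DEL"
        assert r.parent == "father"  # loss of paternal material

    def test_homozygous_deletion(self):
        data = _dataset(child_lrr=-2.5, span=(500, 900))
        r, _ = _annotate(data, _region(500, 900))
        assert r.abn_type == "HD"

    def test_uphd_genotype_match(self):
        # copy-neutral region, child genotypes copy the father's calls
        data = _dataset(child_lrr=0.0, span=(500, 900))
        df = data.df
        gt = df["c_gt"].to_numpy().copy()
        fgt = df["f_gt"].to_numpy().copy()
        fgt[500:901] = np.tile([0, 2], 201)[:401]
        gt[500:901] = fgt[500:901]
        df["c_gt"] = gt
        df["f_gt"] = fgt
        data = TrioDataset(df, data.arms)
        r, _ = _annotate(data, _region(500, 900, parent="father"))
        assert r.abn_type == "UPhD"

    def test_upid_homozygous_fraction(self):
        hom = np.tile(np.array([0, 2], np.int8), 201)[:401]
        data = _dataset(child_lrr=0.008, span=(500, 900),
                        child_baf_fn=lambda rng, n: np.where(
                            hom == 0, rng.normal(0.02, 0.02, n),
                            rng.normal(0.98, 0.02, n)),
                        child_gt=hom)
        r, _ = _annotate(data, _region(500, 900, parent="father"))
        assert r.abn_type == "UPiD"

    def test_copy_neutral_unmatched_is_na(self):
        data = _dataset(child_lrr=0.0, span=(500, 900))
        r, _ = _annotate(data, _region(500, 900, parent="father"))
        assert r.abn_type == "NA"
        assert r.parent_code() == "F(C)"

    def test_partition_single_type(self):
        for lrr in (-2.0, -0.3, 0.0, 0.3):
            data = _dataset(child_lrr=lrr, span=(500, 900))
            r, _ = _annotate(data, _region(500, 900))
            assert r.abn_type in {"AMP", "DEL", "HD", "UPhD", "UPiD", "NA"}

    def test_normalization_shift_invariant(self):
        data = _dataset(child_lrr=0.24, span=(500, 900), seed=4)
        r1, _ = _annotate(data, _region(500, 900))
        df = data.df.copy()
        df["c_lrr"] = df["c_lrr"] + 0.8  # global shift
        shifted = TrioDataset(df, data.arms)
        r2, _ = _annotate(shifted, _region(500, 900))
        assert r2.med_lrr["child"] == pytest.approx(r1.med_lrr["child"],
                                                    abs=1e-9)
        assert r2.abn_type == r1.abn_type


class TestBaselines:
    def test_arm_source_when_mostly_free(self):
        data = _dataset()
        called = np.zeros(2000, bool)
        called[100:200] = True
        assert local_baseline(data, "1q", called, PARAMS).source == "arm"

    def test_adjacent_arm_when_saturated(self):
        rng = np.random.default_rng(0)
        n = 2000
        df = pd.DataFrame({"name": [f"s{i}" for i in range(n)],
                           "chrom": ["1"] * n, "pos": np.arange(n) * 100 + 1})
        for c in "fmc":
            df[f"{c}_gt"] = np.ones(n, np.int8)
            df[f"{c}_baf"] = 0.5
            df[f"{c}_lrr"] = rng.normal(0, 0.1, n)
        data = TrioDataset(df, {"1p": (0, 800), "1q": (800, 2000)})
        called = np.zeros(n, bool)
        called[0:790] = True  # > 75% of 1p
        assert local_baseline(data, "1p", called, PARAMS).source == "adjacent-arm"
        called[:] = True  # whole chromosome: aneuploidy fallback
        assert local_baseline(data, "1p", called, PARAMS).source == "autosomal"


class TestResolveOverlaps:
    def test_pod_yields_to_mi1(self):
        inf = np.zeros(2000, np.int8)
        inf[1000:1100] = 1
        pod = _region(950, 1150, detector="POD")
        mi1 = _region(1000, 1100, detector="PODmi1")
        out = resolve_overlaps([pod, mi1], min_region=200, inf=inf)
        assert [r.detector for r in out] == ["PODmi1"]

    def test_pod_kept_when_informative_outside(self):
        inf = np.zeros(2000, np.int8)
        inf[200:1500] = 1
        pod = _region(200, 1500, detector="POD")
        mi1 = _region(700, 750, detector="PODmi1")
        out = resolve_overlaps([pod, mi1], min_region=10, inf=inf)
        assert any(r.detector == "POD" for r in out)

    def test_hd_passes_through_unfragmented(self):
        inf = np.zeros(2000, np.int8)
        pod = _region(200, 1500, detector="POD")
        hd = _region(600, 640, detector="PODhd")
        out = resolve_overlaps([pod, hd], min_region=10, inf=inf)
        detectors = sorted(r.detector for r in out)
        assert detectors == ["POD", "PODhd"]
        pod_out = next(r for r in out if r.detector == "POD")
        assert pod_out.span == (200, 1500)

    def test_disjoint_untouched(self):
        inf = np.zeros(2000, np.int8)
        a, b = _region(100, 200), _region(300, 400)
        out = resolve_overlaps([a, b], min_region=10, inf=inf)
        assert len(out) == 2

    def test_same_detector_non_nested(self):
        inf = np.zeros(2000, np.int8)
        a = _region(100, 500, parent="father")
        b = _region(300, 800, parent="father")
        out = resolve_overlaps([a, b], min_region=10, inf=inf)
        spans = [r.span for r in out if r.detector == "POD"]
        for i, s1 in enumerate(spans):
            for s2 in spans[i + 1:]:
                assert not (s1[0] <= s2[0] and s2[1] <= s1[1])
                assert not (s2[0] <= s1[0] and s1[1] <= s2[1])


class TestInheritance:
    def _with_types(self, child_lrr, parent, delta, region_parent,
                    other_delta=0.0):
        data = _dataset(child_lrr=child_lrr, span=(500, 900),
                        parent_lrr=(parent, delta))
        other = {"father": "m_lrr", "mother": "f_lrr"}[parent]
        if other_delta:
            arr = data.df[other].to_numpy()
            arr[500:901] += other_delta
            data.df[other] = arr
        r = _region(500, 900, parent=region_parent)
        called = np.zeros(data.n_snps, bool)
        called[500:901] = True
        base = local_baseline(data, "1q", called, PARAMS)
        assign_abnormality_type(r, data, PARAMS, base)
        return assign_inheritance(r, data, base)

    def test_del_inherited(self):
        # detector labels excess mother; origin flips to father, who also
        # carries a deletion at the locus
        r = self._with_types(-0.45, "father", -0.5, "mother")
        assert (r.abn_type, r.parent, r.inheritance) == ("DEL", "father", "INH")

    def test_del_inh_cn(self):
        r = self._with_types(-0.45, "father", -2.2, "mother")
        assert r.inheritance == "INH-CN"

    def test_amp_uninherited_left_blank(self):
        r = self._with_types(0.3, "father", 0.0, "father")
        assert r.abn_type == "AMP" and r.inheritance == ""

    def test_hd_both_parents_del(self):
        data = _dataset(child_lrr=-2.4, span=(500, 900),
                        parent_lrr=("father", -0.5))
        arr = data.df["m_lrr"].to_numpy()
        arr[500:901] += -0.5
        data.df["m_lrr"] = arr
        r = _region(500, 900, parent="both")
        called = np.zeros(data.n_snps, bool)
        called[500:901] = True
        base = local_baseline(data, "1q", called, PARAMS)
        assign_abnormality_type(r, data, PARAMS, base)
        assert assign_inheritance(r, data, base).inheritance == "INH-CN"


class TestParentalArtifactFilter:
    def test_enriched_het_mi1_dropped(self):
        data = _dataset(span=(500, 999), child_lrr=0.0)
        df = data.df
        # het-MI1 signature: both parents AA, child AB, at 20x background
        gt_f = df["f_gt"].to_numpy().copy()
        gt_m = df["m_gt"].to_numpy().copy()
        hits = 500 + np.flatnonzero(
            np.random.default_rng(1).random(500) < 0.05)
        gt_f[hits] = 0
        gt_m[hits] = 0
        df["f_gt"] = gt_f
        df["m_gt"] = gt_m
        data = TrioDataset(df, data.arms)
        keep = filter_parental_artifacts(_region(500, 999), data, PARAMS,
                                         alpha_corr=0.01)
        assert keep is False

    def test_background_rate_kept(self):
        data = _dataset(span=(500, 999))
        keep = filter_parental_artifacts(_region(500, 999), data, PARAMS,
                                         alpha_corr=0.01)
        assert keep is True
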