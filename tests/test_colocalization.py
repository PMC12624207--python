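"""Tests for overlap-based colocalization and synapse typing."""

import numpy as np
import pandas as pd
import pytest

from conftest import disc_mask, random_label_map
from trisyn.colocalization import (
    c_bouton_apposition,
    classify_tripartite,
    coloc_fraction,
    define_synapses,
    pixel_overlap,
    ptdp43_content,
    tripartite_fraction,
)
from trisyn.segmentation import measure_particles


def brute_force_overlap(a, b):
    """Exhaustive pixel-pair scan oracle."""
    pairs = {}
    for y in range(a.shape[0]):
        for x in range(a.shape[1]):
            if a[y, x] > 0 and b[y, x] > 0:
                pairs[(a[y, x], b[y, x])] = pairs.get((a[y, x], b[y, x]), 0) + 1
    return pairs


def records_from(labels, raw=None):
    raw = raw if raw is not None else np.ones(labels.shape)
    t = measure_particles(labels, raw, 0.04)
    return t, labels


class TestPixelOverlap:
    def test_single_shared_pixel_counts(self):
        a = np.zeros((10, 10), dtype=int)
        b = np.zeros((10, 10), dtype=int)
        a[2, 2:5] = 1
        b[2, 4:7] = 1  # share exactly (2,4)
        ov = pixel_overlap(a, b)
        assert len(ov) == 1
        assert ov.loc[0, "overlap_px"] == 1

    def test_disjoint_empty(self):
        a = np.zeros((10, 10), dtype=int)
        b = np.zeros((10, 10), dtype=int)
        a[0, 0] = 1
        b[5, 5] = 1
        assert len(pixel_overlap(a, b)) == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            a = random_label_map(rng)
            b = random_label_map(rng)
            ov = pixel_overlap(a, b)
            expected = brute_force_overlap(a, b)
            got = {
                (row.label_a, row.label_b): row.overlap_px for row in ov.itertuples()
            }
            assert got == expected

    def test_symmetry(self, rng):
        a = random_label_map(rng)
        b = random_label_map(rng)
        ab = {(r.label_a, r.label_b) for r in pixel_overlap(a, b).itertuples()}
        ba = {(r.label_b, r.label_a) for r in pixel_overlap(b, a).itertuples()}
        assert ab == ba


class TestColocFraction:
    def test_no_partners_zero(self):
        a = np.zeros((10, 10), dtype=int)
        a[1, 1:4] = 1
        assert coloc_fraction(a, np.zeros_like(a)) == 0.0

    def test_all_overlapped_one(self):
        a = np.zeros((10, 10), dtype=int)
        a[1, 1:4] = 1
        a[5, 1:4] = 2
        b = (a > 0).astype(int)
        assert coloc_fraction(a, b) == 1.0

    def test_empty_a_raises(self):
        with pytest.raises(ValueError, match="no particles"):
            coloc_fraction(np.zeros((5, 5), dtype=int), np.zeros((5, 5), dtype=int))

    def test_binomial_recovery_at_p06(self, rng):
        # 200 discs; each gets an overlapping partner with p = 0.6
        p = 0.6
        shape = (300, 300)
        a = np.zeros(shape, dtype=int)
        b = np.zeros(shape, dtype=int)
        n = 0
        for gy in range(1, 15):
            for gx in range(1, 15):
                if n >= 200:
                    break
                n += 1
                cy, cx = gy * 20, gx * 20
                a[disc_mask(shape, cy, cx, 3)] = n
                if rng.random() < p:
                    b[disc_mask(shape, cy + 2, cx + 2, 3)] = n
        frac = coloc_fraction(a, b)
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / 200)


class TestDefineSynapses:
    def _simple_maps(self):
        pre = np.zeros((30, 30), dtype=int)
        psd = np.zeros((30, 30), dtype=int)
        pre[5, 5:10] = 1  # overlaps two PSDs
        pre[20, 5:10] = 2  # overlaps nothing
        psd[5, 5:7] = 1  # 2 px
        psd[5, 8:14] = 2  # 6 px, larger
        return pre, psd

    def test_psd_flags_and_largest_partner(self):
        pre, psd = self._simple_maps()
        pre_t, _ = records_from(pre)
        psd_t, _ = records_from(psd)
        rec = define_synapses(pre_t, pre, psd_t, psd).set_index("label")
        assert bool(rec.loc[1, "has_psd"]) is True
        assert bool(rec.loc[2, "has_psd"]) is False
        # psd area = larger overlapping PSD (6 px)
        assert rec.loc[1, "psd_area_um2"] == pytest.approx(6 * 0.04**2)

    def test_tie_broken_by_lowest_label(self):
        pre = np.zeros((20, 20), dtype=int)
        psd = np.zeros((20, 20), dtype=int)
        pre[5, 2:12] = 1
        psd[5, 2:5] = 1  # 3 px
        psd[5, 8:11] = 2  # 3 px, same area
        pre_t, _ = records_from(pre)
        psd_t, _ = records_from(psd)
        rec = define_synapses(pre_t, pre, psd_t, psd)
        assert rec.loc[0, "psd_area_um2"] == pytest.approx(3 * 0.04**2)


class TestClassifyTripartite:
    def test_no_pap_all_nontripartite(self):
        pre, psd = TestDefineSynapses()._simple_maps()
        pre_t, _ = records_from(pre)
        psd_t, _ = records_from(psd)
        rec = define_synapses(pre_t, pre, psd_t, psd)
        rec = classify_tripartite(rec, pre, np.zeros_like(pre))
        assert not rec["is_tripartite"].any()
        assert tripartite_fraction(rec) == 0.0

    def test_partition_tri_plus_nontri_equals_bona_fide(self, rng):
        pre = random_label_map(rng, (64, 64))
        psd = random_label_map(rng, (64, 64))
        pap = random_label_map(rng, (64, 64))
        pre_t, _ = records_from(pre)
        psd_t, _ = records_from(psd)
        rec = define_synapses(pre_t, pre, psd_t, psd)
        rec = classify_tripartite(rec, pre, pap)
        bona = rec[rec["has_psd"]]
        n_tri = int((bona["is_tripartite"]).sum())
        n_non = int((~bona["is_tripartite"]).sum())
        assert n_tri + n_non == len(bona)


class TestCBoutonApposition:
    def _setup(self):
        shape = (40, 40)
        soma = disc_mask(shape, 20, 20, 10)
        labels = np.zeros(shape, dtype=int)
        labels[disc_mask(shape, 20, 28, 1)] = 1  # 1-2 px inside boundary
        labels[disc_mask(shape, 20, 33, 1)] = 2  # 2 px outside boundary
        labels[disc_mask(shape, 5, 5, 1)] = 3  # far away
        t = measure_particles(labels, np.ones(shape), 0.04)
        return t, labels, soma

    def test_inside_apposed_at_dilation_zero(self):
        t, labels, soma = self._setup()
        rec = c_bouton_apposition(t, labels, soma, dilation_px=0).set_index("label")
        assert bool(rec.loc[1, "apposed"]) is True
        assert bool(rec.loc[2, "apposed"]) is False

    def test_outside_needs_dilation(self):
        t, labels, soma = self._setup()
        rec0 = c_bouton_apposition(t, labels, soma, 0).set_index("label")
        rec2 = c_bouton_apposition(t, labels, soma, 2).set_index("label")
        # oracle: explicit dilation of the soma mask
        from scipy import ndimage as ndi
        from skimage.morphology import disk as _disk

        dil = ndi.binary_dilation(soma, structure=_disk(2))
        assert bool(rec2.loc[2, "apposed"]) is bool((dil & (labels == 2)).any())
        assert bool(rec0.loc[2, "apposed"]) is False
        assert bool(rec2.loc[2, "apposed"]) is True
        assert bool(rec2.loc[3, "apposed"]) is False

    def test_empty_soma_mask_none_apposed(self):
        t, labels, _ = self._setup()
        rec = c_bouton_apposition(t, labels, np.zeros(labels.shape, dtype=bool), 2)
        assert not rec["apposed"].any()

    def test_monotone_in_dilation(self):
        t, labels, soma = self._setup()
        sets = []
        for d in (0, 1, 2, 4):
            rec = c_bouton_apposition(t, labels, soma, d)
            sets.append(set(rec.loc[rec["apposed"], "label"]))
        for s0, s1 in zip(sets, sets[1:]):
            assert s0 <= s1


class TestPtdp43Content:
    def test_cluster_counts_and_shared_cluster(self):
        shape = (30, 30)
        pre = np.zeros(shape, dtype=int)
        ptdp = np.zeros(shape, dtype=int)
        pre[5, 2:12] = 1
        pre[5, 12:20] = 2
        # three clusters on bouton 1; one spanning boutons 1 and 2
        ptdp[5, 2] = 1
        ptdp[5, 5] = 2
        ptdp[5, 8] = 3
        ptdp[5, 11:14] = 4  # spans the 1|2 boundary
        pre_t, _ = records_from(pre)
        ptdp_t, _ = records_from(ptdp)
        rec = ptdp43_content(pre_t.rename(columns={"area_um2": "bouton_area_um2"}), pre, ptdp_t, ptdp).set_index("label")
        assert rec.loc[1, "n_ptdp43_clusters"] == 4
        assert rec.loc[2, "n_ptdp43_clusters"] == 1  # shared cluster counted for both
        assert len(rec.loc[1, "ptdp43_cluster_areas_um2"]) == 4

    def test_no_clusters(self):
        pre = np.zeros((10, 10), dtype=int)
        pre[2, 2:6] = 1
        pre_t, _ = records_from(pre)
        empty_t, _ = records_from(np.zeros_like(pre))
        rec = ptdp43_content(pre_t.rename(columns={"area_um2": "bouton_area_um2"}), pre, empty_t, np.zeros_like(pre))
        assert rec["n_ptdp43_clusters"].tolist() == [0]
        assert rec["ptdp43_cluster_areas_um2"].tolist() == [[]]
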