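"""Image-quantification unit tests: each algorithm against an independent
brute-force oracle, plus the degenerate branches of the stated contracts."""

import numpy as np
import pandas as pd
import pytest

from borderquant.imagequant import (
    ColocConfig,
    ImageStack,
    bernsen_local_threshold,
    call_nuclei,
    colocalization_fraction,
    image_histogram,
    label_components,
    max_intensity_projection,
    read_image_stack,
    renyi_entropy_threshold,
    sample_regions,
    summarize_stages,
    tukey_outliers,
    write_image_stack,
)
from borderquant.imagequant import _renyi_argmax  # per-alpha criterion under test


# ---------------------------------------------------------------------------
# Renyi entropy thresholding


def oracle_renyi_argmax(hist, alpha):
    """Independent brute force: plain-Python entropy sums over all splits."""
    import math

    p = [h / sum(hist) for h in hist]
    occ = [i for i, h in enumerate(hist) if h > 0]
    best_t, best = None, -math.inf
    for t in range(occ[0], occ[-1]):
        p1 = sum(p[: t + 1])
        p2 = sum(p[t + 1 :])
        if alpha == 1.0:
            hb = -sum(x / p1 * math.log(x / p1) for x in p[: t + 1] if x > 0)
            hf = -sum(x / p2 * math.log(x / p2) for x in p[t + 1 :] if x > 0)
            val = hb + hf
        else:
            sb = sum((x / p1) ** alpha for x in p[: t + 1])
            sf = sum((x / p2) ** alpha for x in p[t + 1 :])
            val = (math.log(sb) + math.log(sf)) / (1.0 - alpha)
        if val > best:
            best, best_t = val, t
    return best_t


@pytest.mark.parametrize("alpha", [1.0, 0.5, 2.0])
def test_renyi_per_alpha_matches_bruteforce(rng, alpha):
    for _ in range(100):
        hist = rng.integers(0, 50, size=8)
        if np.count_nonzero(hist) < 2:
            continue
        p = hist / hist.sum()
        cum = np.cumsum(p)
        assert _renyi_argmax(p, cum, alpha) == oracle_renyi_argmax(hist.tolist(), alpha)


def test_renyi_two_delta_histogram():
    hist = np.zeros(256)
    hist[10] = 40
    hist[200] = 60
    thr, degenerate = renyi_entropy_threshold(hist)
    assert not degenerate
    assert 10 <= thr <= 199  # foreground (strictly above) is exactly the 200-bin


def test_renyi_single_bin_warns():
    hist = np.zeros(256)
    hist[37] = 100
    with pytest.warns(UserWarning):
        thr, degenerate = renyi_entropy_threshold(hist)
    assert degenerate and thr == 37


def test_renyi_rejects_empty():
    with pytest.raises(ValueError):
        renyi_entropy_threshold(np.zeros(256))


# ---------------------------------------------------------------------------
# Bernsen local thresholding


def oracle_bernsen(img, radius, contrast, bit_depth=8):
    h, w = img.shape
    out = np.zeros((h, w), bool)
    gmid = (2**bit_depth - 1) / 2
    for i in range(h):
        for j in range(w):
            i0, i1 = max(0, i - radius), min(h, i + radius + 1)
            j0, j1 = max(0, j - radius), min(w, j + radius + 1)
            win = img[i0:i1, j0:j1]
            lo, hi = win.min(), win.max()
            mid = (float(lo) + float(hi)) / 2
            if hi - lo >= contrast:
                out[i, j] = img[i, j] >= mid
            else:
                out[i, j] = mid >= gmid
    return out


def test_bernsen_matches_pixel_oracle(rng):
    for _ in range(5):
        img = rng.integers(0, 256, size=(32, 32)).astype(float)
        got = bernsen_local_threshold(img, radius=3, contrast_threshold=15)
        assert np.array_equal(got, oracle_bernsen(img, 3, 15))


def test_bernsen_constant_image_low_contrast_branch():
    img = np.full((20, 20), 40.0)
    assert not bernsen_local_threshold(img, radius=2).any()
    bright = np.full((20, 20), 200.0)
    assert bernsen_local_threshold(bright, radius=2).all()


def test_bernsen_bright_square_on_dark_field():
    img = np.zeros((21, 21))
    img[7:14, 7:14] = 200.0
    mask = bernsen_local_threshold(img, radius=3, contrast_threshold=15)
    assert mask[7:14, 7:14].all()
    assert not mask[0:3, 0:3].any()


def test_bernsen_edge_clamp_matches_oracle(rng):
    img = rng.integers(0, 256, size=(16, 16)).astype(float)
    got = bernsen_local_threshold(img, radius=5, contrast_threshold=30)
    assert np.array_equal(got, oracle_bernsen(img, 5, 30))


# ---------------------------------------------------------------------------
# connected components


def oracle_flood_fill(mask, connectivity, min_size):
    from collections import deque

    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    seen = np.zeros((h, w), bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                q = deque([(i, j)])
                seen[i, j] = True
                comp = []
                while q:
                    ci, cj = q.popleft()
                    comp.append((ci, cj))
                    for di, dj in steps:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            q.append((ni, nj))
                if len(comp) >= min_size:
                    comps.append(sorted(comp))
    return comps


@pytest.mark.parametrize("connectivity", [4, 8])
def test_label_components_matches_flood_fill(rng, connectivity):
    for _ in range(20):
        mask = rng.random((24, 24)) < 0.35
        labels = label_components(mask, connectivity, min_size=5)
        got = []
        for lab in range(1, labels.max() + 1):
            got.append(sorted(map(tuple, np.argwhere(labels == lab))))
        expected = oracle_flood_fill(mask, connectivity, 5)
        assert sorted(got) == sorted(expected)


def test_label_components_size_filter():
    mask = np.zeros((20, 20), bool)
    mask[1:6, 1:6] = True  # 25 px
    assert label_components(mask, 8, min_size=20).max() == 1
    mask2 = np.zeros((20, 20), bool)
    mask2[1:5, 1:5] = True  # 16 px < 20
    assert label_components(mask2, 8, min_size=20).max() == 0


# ---------------------------------------------------------------------------
# nucleus calling on generator images


def test_call_nuclei_recovers_count_and_labels(noiseless_explant):
    params, stack, truth = noiseless_explant
    nuclei = call_nuclei(stack)
    assert len(nuclei) == params.n_nuclei
    assert nuclei["id"].tolist() == list(range(1, params.n_nuclei + 1))
    assert (nuclei["area"] >= 20).all()
    assert int(nuclei["pax3_positive"].sum()) == int(truth.pax3.sum())
    assert int(nuclei["sox3_positive"].sum()) == int(truth.sox3.sum())


def test_call_nuclei_all_double_positive():
    from borderquant.synthetic_data import ExplantImageParams, make_explant_image

    params = ExplantImageParams(
        width=256, height=256, n_nuclei=60, noise_sd=0.0,
        frac_pax3=1.0, frac_double_given_pax3=1.0, seed=2,
    )
    stack, _ = make_explant_image(params)
    nuclei = call_nuclei(stack)
    assert nuclei["pax3_positive"].all() and nuclei["sox3_positive"].all()


def test_call_nuclei_early_gastrula_like_all_pax3_are_sox3():
    # early-gastrula condition: every nucleus with nascent pax3 is Sox3+
    from borderquant.synthetic_data import explant_params_for_stage, make_explant_image

    params = explant_params_for_stage("10.5", seed=9, n_nuclei=120, width=384, height=384)
    stack, _ = make_explant_image(params)
    nuclei = call_nuclei(stack)
    pax = nuclei[nuclei["pax3_positive"]]
    assert len(pax) > 0
    assert pax["sox3_positive"].all()


def test_noiseless_recovery_across_stage_profile():
    """On noiseless 300-nucleus explants at every stage of the ground-truth
    profile, the recovered mean region fraction stays within 0.05 of the
    image's true double-positive fraction."""
    from borderquant.imagequant import sample_regions as sr
    from borderquant.synthetic_data import FIG1C_PROFILE, explant_params_for_stage, make_explant_image

    for stage in FIG1C_PROFILE:
        params = explant_params_for_stage(stage, seed=31, n_nuclei=300, noise_sd=0.0)
        stack, truth = make_explant_image(params)
        nuclei = call_nuclei(stack)
        regions = sr(nuclei, 3, 50, seed=32)
        res = colocalization_fraction(nuclei, regions)
        mean = np.nanmean(res["fraction"])
        assert abs(mean - truth.true_double_fraction) <= 0.05, stage


def test_call_nuclei_empty_image_warns():
    blank = np.full((64, 64), 10, dtype=np.uint16)
    stack = ImageStack(dapi=blank, sox3=blank, pax3=blank)
    with pytest.warns(UserWarning):
        nuclei = call_nuclei(stack)
    assert nuclei.empty


# ---------------------------------------------------------------------------
# region sampling


def _toy_nuclei(rng, n=120):
    return pd.DataFrame(
        dict(
            id=np.arange(1, n + 1),
            row=rng.uniform(0, 200, n),
            col=rng.uniform(0, 200, n),
            area=np.full(n, 30),
            pax3_positive=rng.random(n) < 0.5,
            sox3_positive=rng.random(n) < 0.5,
        )
    )


def test_sample_regions_matches_distance_sort_oracle(rng):
    nuclei = _toy_nuclei(rng)
    regions = sample_regions(nuclei, n_regions=3, cells_per_region=20, seed=4)
    coords = nuclei.set_index("id")[["row", "col"]]
    for reg in regions.values():
        seed_xy = coords.loc[reg["seed_id"]].to_numpy()
        d = np.hypot(*(coords.to_numpy() - seed_xy).T)
        order = sorted(zip(d, coords.index))  # distance then lower id
        expected = {gid for _, gid in order[:20]}
        assert reg["members"] == expected


def test_sample_regions_forced_coverage(rng):
    nuclei = _toy_nuclei(rng, n=50)
    regions = sample_regions(nuclei, n_regions=3, cells_per_region=50, seed=0)
    for reg in regions.values():
        assert reg["members"] == set(range(1, 51))


def test_sample_regions_deterministic(rng):
    nuclei = _toy_nuclei(rng)
    a = sample_regions(nuclei, 3, 30, seed=11)
    b = sample_regions(nuclei, 3, 30, seed=11)
    assert a == b


def test_sample_regions_too_few_nuclei_errors(rng):
    nuclei = _toy_nuclei(rng, n=10)
    with pytest.raises(ValueError, match="50 cells from 10"):
        sample_regions(nuclei, 3, 50, seed=0)


# ---------------------------------------------------------------------------
# colocalization statistic and stage summaries


def test_colocalization_fraction_counts_and_na(rng):
    nuclei = _toy_nuclei(rng, n=40)
    nuclei.loc[:, "pax3_positive"] = False
    nuclei.loc[:9, "pax3_positive"] = True
    nuclei.loc[:, "sox3_positive"] = False
    nuclei.loc[:4, "sox3_positive"] = True
    regions = {1: {"seed_id": 1, "members": set(range(1, 21))},
               2: {"seed_id": 30, "members": set(range(21, 41))}}
    res = colocalization_fraction(nuclei, regions)
    r1 = res[res.region == 1].iloc[0]
    assert r1.n_pax3 == 10 and r1.n_double == 5 and r1.fraction == 0.5
    r2 = res[res.region == 2].iloc[0]
    assert r2.n_pax3 == 0 and np.isnan(r2.fraction)
    # count conservation
    assert (res["n_double"] <= res[["n_pax3", "n_sox3"]].min(axis=1)).all()
    assert (res[["n_pax3", "n_sox3"]].max(axis=1) <= res["n_dapi"]).all()


def test_colocalization_fraction_all_double(rng):
    nuclei = _toy_nuclei(rng, n=30)
    nuclei["sox3_positive"] = nuclei["pax3_positive"]
    regions = {1: {"seed_id": 1, "members": set(range(1, 31))}}
    res = colocalization_fraction(nuclei, regions)
    assert res["fraction"].iloc[0] == 1.0


def test_colocalization_fraction_unknown_nucleus_errors(rng):
    nuclei = _toy_nuclei(rng, n=10)
    with pytest.raises(ValueError, match="unknown nuclei"):
        colocalization_fraction(nuclei, {1: {"seed_id": 1, "members": {1, 99}}})


def test_tukey_outlier_flagging_matches_quartile_oracle():
    vals = np.array([0.5] * 17 + [0.99])
    flags = tukey_outliers(vals)
    q1, q3 = np.percentile(vals, [25, 75])
    expected = (vals < q1 - 1.5 * (q3 - q1)) | (vals > q3 + 1.5 * (q3 - q1))
    assert np.array_equal(flags, expected)
    assert flags.sum() == 1 and flags[-1]
    assert not tukey_outliers(np.full(18, 0.4)).any()


def test_summarize_stages_means_and_errors():
    out = summarize_stages({"a": [0.5, 0.6, np.nan], "b": [0.2, 0.2]})
    assert out.set_index("stage").loc["a", "n"] == 2
    assert out.set_index("stage").loc["b", "mean"] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        summarize_stages({"bad": [np.nan]})


# ---------------------------------------------------------------------------
# stack plumbing


def test_image_stack_validation():
    a = np.zeros((10, 10), np.uint16)
    with pytest.raises(ValueError, match="shapes differ"):
        ImageStack(dapi=a, sox3=a, pax3=np.zeros((5, 5), np.uint16))


def test_max_intensity_projection():
    z = np.stack([np.full((4, 4), i) for i in (1, 5, 3)])
    assert (max_intensity_projection(z) == 5).all()


def test_tiff_round_trip(tmp_path, noiseless_explant):
    _, stack, _ = noiseless_explant
    path = tmp_path / "explant.tiff"
    write_image_stack(path, stack)
    back = read_image_stack(path)
    for ch in ("dapi", "sox3", "pax3"):
        assert np.array_equal(back.channel(ch), stack.channel(ch))


def test_histogram_covers_full_bit_range():
    img = np.array([[0, 255], [128, 128]])
    h = image_histogram(img)
    assert h[0] == 1 and h[255] == 1 and h[128] == 2 and h.sum() == 4
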