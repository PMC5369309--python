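import numpy as np
import pytest

from momchannel import (
    CellState,
    MeasurementError,
    OpticsParams,
    PipelineError,
    SegmentationParams,
    TimeLapseStack,
    axial_profile,
    detect_boundaries,
    make_masks,
    measure_cell,
    preprocess_frame,
    render_frame,
    segment_frame,
    segment_stack,
    simulate_stack,
)
from momchannel.segmentation import _moment_length


def quiet_optics(**overrides) -> OpticsParams:
    base = dict(psf_sigma_px=1.0, read_noise_sd=0.0, shot_noise=False)
    base.update(overrides)
    return OpticsParams(**base)


# ---------------------------------------------------------------------------
# preprocess_frame


def test_median_filter_removes_hot_pixel():
    img = np.full((20, 20), 10.0)
    img[10, 10] = 10_000.0
    out = preprocess_frame(img)
    # the hot pixel was replaced before rescaling: the frame is constant
    assert out[10, 10] == out[0, 0]


def test_rescale_saturates_two_percent_tails():
    """On a linear ramp the saturated pixel counts match an independent
    percentile computation."""
    img = np.linspace(0.0, 1.0, 10_000).reshape(100, 100)
    p = SegmentationParams(median_kernel=1)
    out = preprocess_frame(img, p)
    lo, hi = np.percentile(img, [2, 98])
    expected_zero = int((img <= lo).sum())
    expected_one = int((img >= hi).sum())
    assert abs(int((out == 0.0).sum()) - expected_zero) <= 2
    assert abs(int((out == 1.0).sum()) - expected_one) <= 2
    assert out.min() == 0.0 and out.max() == 1.0


def test_constant_frame_warns_and_returns_zeros():
    with pytest.warns(UserWarning):
        out = preprocess_frame(np.full((10, 10), 7.0))
    np.testing.assert_array_equal(out, np.zeros((10, 10)))


def test_rescale_is_monotone(rng):
    img = rng.uniform(0, 1000, size=(30, 10))
    p = SegmentationParams(median_kernel=1)  # isolate the rescale step
    out = preprocess_frame(img, p)
    i = np.argsort(img.ravel())
    assert np.all(np.diff(out.ravel()[i]) >= 0)


# ---------------------------------------------------------------------------
# axial_profile


def test_profile_constant_and_bright_row():
    assert np.allclose(axial_profile(np.full((8, 4), 3.0)), 3.0)
    img = np.zeros((10, 5))
    img[6] = 9.0
    assert int(np.argmax(axial_profile(img))) == 6


def test_profile_matches_brute_force_row_means():
    stack, _ = simulate_stack(n_generations=3, seed=0)
    img = preprocess_frame(stack.frames[-1])
    prof = axial_profile(img)
    oracle = np.array([img[i].mean() for i in range(img.shape[0])])
    np.testing.assert_allclose(prof, oracle)


# ---------------------------------------------------------------------------
# detect_boundaries


def test_monotone_profile_has_no_boundaries():
    prof = np.linspace(0.1, 1.0, 50)
    assert detect_boundaries(prof).size == 0


def test_v_profile_single_minimum():
    prof = np.concatenate([np.linspace(1.0, 0.5, 21), np.linspace(0.5, 1.0, 21)[1:]])
    b = detect_boundaries(prof)
    np.testing.assert_array_equal(b, [20])


def test_background_minima_discarded():
    prof = np.concatenate([np.full(20, 1.0), np.full(30, 0.02)])
    prof[35] = 0.0  # a dip deep in the background region
    assert detect_boundaries(prof).size == 0


def test_boundary_within_one_pixel_of_true_interface():
    o = quiet_optics(septum_dip=0.3)
    cells = [CellState(0.0, 28.0, 100.0), CellState(28.0, 26.0, 100.0)]
    img = render_frame(cells, o)
    prof = axial_profile(preprocess_frame(img))
    b = detect_boundaries(prof)
    assert len(b) == 1
    assert abs(b[0] - 28) <= 1


# ---------------------------------------------------------------------------
# make_masks / measure_cell


def test_blank_frame_yields_no_masks():
    assert make_masks(np.zeros((30, 10)), np.array([])) == []


def test_single_tophat_mask_covers_support():
    img = np.zeros((40, 9))
    img[10:25, 2:7] = 1.0
    masks = make_masks(img, np.array([]))
    assert len(masks) == 1
    np.testing.assert_array_equal(masks[0], img > 0.5)


def test_lower_threshold_gives_nested_larger_masks():
    o = quiet_optics(psf_sigma_px=1.5)
    img = render_frame([CellState(30.5, 30.0, 100.0)], o)
    resc = preprocess_frame(img)
    m_low = make_masks(resc, np.array([]), SegmentationParams(threshold_rel=0.2))[0]
    m_high = make_masks(resc, np.array([]), SegmentationParams(threshold_rel=0.3))[0]
    assert m_low.sum() > m_high.sum()
    assert np.all(m_low[m_high])  # nestedness
    c_low = measure_cell(m_low, img)
    c_high = measure_cell(m_high, img)
    assert c_low.length > c_high.length
    assert c_low.mean_fluor < c_high.mean_fluor


def test_measure_uniform_cell_and_single_pixel():
    raw = np.full((20, 8), 5.0)
    mask = np.zeros((20, 8), dtype=bool)
    mask[4:16, 2:6] = True
    m = measure_cell(mask, raw)
    assert m.mean_fluor == pytest.approx(5.0)
    assert m.area_px == 12 * 4
    assert m.axial_span == (4, 16)
    single = np.zeros((20, 8), dtype=bool)
    single[3, 3] = True
    s = measure_cell(single, raw)
    assert s.area_px == 1
    assert s.total_fluor == s.mean_fluor == pytest.approx(5.0)
    assert s.length == pytest.approx(1.0)


def test_rod_length_exact_on_rectangle():
    mask = np.zeros((60, 12), dtype=bool)
    mask[5:45, 2:10] = True
    assert _moment_length(mask, "rod") == pytest.approx(40.0)


def test_ellipse_length_matches_second_moment_oracle():
    """Major-axis length of a 40x8 rectangle vs brute-force covariance."""
    mask = np.zeros((60, 12), dtype=bool)
    mask[5:45, 2:10] = True
    ax, tr = np.nonzero(mask)
    pts = np.stack([ax, tr]).astype(float)
    pts -= pts.mean(axis=1, keepdims=True)
    cov = pts @ pts.T / pts.shape[1] + np.eye(2) / 12.0
    oracle = 4.0 * np.sqrt(np.linalg.eigvalsh(cov)[-1])
    impl = _moment_length(mask, "ellipse")
    assert impl == pytest.approx(oracle, rel=0.02)
    # and skimage's region property uses the same ellipse convention
    from skimage.measure import regionprops

    rp = regionprops(mask.astype(int))[0]
    assert impl == pytest.approx(rp.axis_major_length, rel=0.02)


def test_empty_mask_raises():
    with pytest.raises(MeasurementError):
        measure_cell(np.zeros((5, 5), dtype=bool), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# segment_frame / segment_stack


def test_blank_frame_segments_empty(rng):
    img = rng.normal(100.0, 1.0, size=(50, 15))
    seg = segment_frame(img)
    assert seg.n_cells == 0


def test_three_cell_frame_ordered_disjoint():
    o = quiet_optics()
    cells = [CellState(0.0, 26.0, 100.0), CellState(26.0, 24.0, 95.0),
             CellState(50.0, 27.0, 105.0)]
    img = render_frame(cells, o)
    seg = segment_frame(img)
    assert seg.n_cells == 3
    spans = [c.axial_span for c in seg.cells]
    assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
    assert [c.index_from_closed_end for c in seg.cells] == [0, 1, 2]


def test_mirrored_frame_equivariance():
    """Flipping the channel (closed end at the far index) preserves
    measurements and mirrors the spans."""
    o = quiet_optics()
    cells = [CellState(0.0, 26.0, 100.0), CellState(26.0, 24.0, 95.0)]
    img = render_frame(cells, o)
    seg = segment_frame(img, closed_end="low")
    seg_flipped = segment_frame(img[::-1], closed_end="high")
    assert seg.n_cells == seg_flipped.n_cells
    n = img.shape[0]
    for a, b in zip(seg.cells, seg_flipped.cells):
        assert a.length == pytest.approx(b.length)
        assert a.mean_fluor == pytest.approx(b.mean_fluor)
        assert b.axial_span == (n - a.axial_span[1], n - a.axial_span[0])


def test_channel_axis_one_transposed_frame():
    o = quiet_optics()
    img = render_frame([CellState(5.0, 30.0, 100.0)], o)
    seg0 = segment_frame(img, channel_axis=0)
    seg1 = segment_frame(img.T, channel_axis=1)
    assert seg0.n_cells == seg1.n_cells == 1
    assert seg0.cells[0].length == pytest.approx(seg1.cells[0].length)


def test_segment_stack_clean_has_no_gaps(clean_stack_and_truth):
    stack, truth = clean_stack_and_truth
    series = segment_stack(stack)
    assert series.n_gaps == 0
    rmse = np.sqrt(np.mean((series.length - truth.length) ** 2))
    assert rmse <= 1.0


def test_segment_stack_flags_injected_blank_frame(default_stack_and_truth):
    stack, _ = default_stack_and_truth
    frames = stack.frames.copy()
    frames[5] = 0
    broken = TimeLapseStack(frames=frames, times=stack.times)
    series = segment_stack(broken)
    assert series.n_gaps == 1
    assert bool(series.gap_flags[5])
    trace = series.to_trace()
    assert trace.length[5] == trace.length[4]  # carried, not interpolated


def test_unusable_stack_raises():
    frames = np.zeros((10, 50, 15), dtype=np.uint16)
    stack = TimeLapseStack(frames=frames, times=np.arange(10.0))
    with pytest.raises(PipelineError):
        segment_stack(stack)
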