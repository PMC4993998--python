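import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcfmtex.io import fov_mask
from fcfmtex.lbp import (
    LBPConfig,
    frame_lbp_histogram,
    lbp_code,
    riu2_bin,
    video_lbp_feature,
)


# -- independent brute-force oracle (own interpolation + transition count) ----

def _oracle_histogram(frame, mask, R, P):
    frame = frame.astype(float)
    h, w = frame.shape
    hist = np.zeros(P + 2)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            if y - R < 0 or y + R > h - 1 or x - R < 0 or x + R > w - 1:
                continue
            bits = []
            for p in range(P):
                ang = 2 * np.pi * p / P
                ny, nx = y - R * np.sin(ang), x + R * np.cos(ang)
                y0, x0 = int(np.floor(ny)), int(np.floor(nx))
                fy, fx = ny - y0, nx - x0
                y1 = min(y0 + 1, h - 1)
                x1 = min(x0 + 1, w - 1)
                val = (frame[y0, x0] * (1 - fy) * (1 - fx)
                       + frame[y0, x1] * (1 - fy) * fx
                       + frame[y1, x0] * fy * (1 - fx)
                       + frame[y1, x1] * fy * fx)
                bits.append(1 if val >= frame[y, x] else 0)
            trans = sum(bits[i] != bits[(i + 1) % P] for i in range(P))
            hist[sum(bits) if trans <= 2 else P + 1] += 1
    return hist / hist.sum()


def test_histogram_matches_bruteforce_oracle(rng):
    frame = rng.uniform(0, 255, (16, 16))
    mask = fov_mask((16, 16))
    got = frame_lbp_histogram(frame, mask, R=1, P=8)
    want = _oracle_histogram(frame, mask, 1, 8)
    np.testing.assert_allclose(got, want, atol=1e-12)


@pytest.mark.parametrize("R,P", [(2, 16), (3, 24)])
def test_histogram_matches_oracle_larger_radii(rng, R, P):
    frame = rng.uniform(0, 1, (20, 20))
    mask = fov_mask((20, 20))
    np.testing.assert_allclose(
        frame_lbp_histogram(frame, mask, R, P), _oracle_histogram(frame, mask, R, P),
        atol=1e-12,
    )


# -- scalar code / bin mapping -----------------------------------------------

def test_lbp_code_3x3_axial_neighbours():
    frame = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
    code = lbp_code(frame, (1, 1), R=1, P=4)
    # neighbours right,up,left,down = 6,2,4,8 vs centre 5 -> bits (1,0,0,1)
    assert code == 0b1001


def test_lbp_code_ties_count_as_one():
    assert lbp_code(np.full((3, 3), 7.0), (1, 1), 1, 8) == 0xFF


def test_lbp_code_bright_centre_is_zero():
    f = np.zeros((3, 3))
    f[1, 1] = 10
    assert lbp_code(f, (1, 1), 1, 8) == 0


def test_lbp_code_circle_outside_frame_raises():
    with pytest.raises(ValueError):
        lbp_code(np.zeros((3, 3)), (0, 0), 1, 8)


def test_riu2_reference_patterns():
    assert riu2_bin(0b00110000, 8) == 2  # two transitions, two set bits
    assert riu2_bin(0b00000000, 8) == 0
    assert riu2_bin(0b11111111, 8) == 8
    assert riu2_bin(0b01010101, 8) == 9  # 8 transitions -> miscellaneous


@settings(max_examples=200, deadline=None, derandomize=True)
@given(code=st.integers(0, 2**8 - 1))
def test_riu2_bin_range_and_uniform_popcount(code):
    b = riu2_bin(code, 8)
    assert 0 <= b <= 9
    bits = [(code >> p) & 1 for p in range(8)]
    if b <= 8:  # uniform: bin equals popcount
        assert b == sum(bits)


# -- histograms / features ----------------------------------------------------

def test_constant_frame_all_mass_in_bin_P():
    mask = fov_mask((16, 16))
    h = frame_lbp_histogram(np.full((16, 16), 3.0), mask, 1, 8)
    assert h[8] == 1.0 and h.sum() == 1.0


def test_intensity_scale_and_shift_invariance(rng):
    frame = rng.uniform(0, 1, (32, 32))
    mask = fov_mask((32, 32))
    base = frame_lbp_histogram(frame, mask, 2, 16)
    np.testing.assert_allclose(base, frame_lbp_histogram(3.7 * frame, mask, 2, 16))
    np.testing.assert_allclose(base, frame_lbp_histogram(frame + 11.0, mask, 2, 16))


def test_rotation_approximate_invariance(tiny_cohort):
    v = tiny_cohort.videos[0]
    frame = v.frames[v.on_target_indices[0]].astype(float)
    mask = fov_mask(frame.shape)
    for R, P in [(1, 8), (2, 16)]:
        a = frame_lbp_histogram(frame, mask, R, P)
        b = frame_lbp_histogram(np.rot90(frame), mask, R, P)
        assert 0.5 * np.abs(a - b).sum() < 0.02  # total variation


def test_video_feature_blocks_and_pooling(tiny_cohort):
    v = tiny_cohort.videos[0]
    feat = video_lbp_feature(v)
    assert feat.vector.size == 80
    ofs = 0
    for _, P in LBPConfig().resolutions:
        assert abs(feat.vector[ofs : ofs + P + 2].sum() - 1.0) < 1e-9
        ofs += P + 2
    # single-frame video equals that frame's histograms; duplicates change nothing
    from fcfmtex.io import FCFMVideo

    one = FCFMVideo("a", v.frames[:1], [(0, 1)])
    two = FCFMVideo("b", np.repeat(v.frames[:1], 2, axis=0), [(0, 2)])
    np.testing.assert_allclose(
        video_lbp_feature(one).vector, video_lbp_feature(two).vector, atol=1e-12
    )
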