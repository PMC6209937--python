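"""Stage-1 unit and oracle tests: thresholding, clustering, Radon line
detection, ellipse fitting and ROI filtering."""

import math

import numpy as np
import pytest
from skimage.draw import disk, line as draw_line

from needleloc.core import EllipseROI, ImageGrid, LineEstimate
from needleloc.doppler_axis import (DbscanParams, PixelCluster, cluster_doppler,
                                    filter_rois, fit_ellipse, initial_axis,
                                    intermeans_threshold, preprocess_doppler,
                                    radon_line_detect)


def grid(arr, spacing=1.0):
    return ImageGrid(np.asarray(arr, dtype=float), spacing)


# ------------------------------------------------------------ thresholding

class TestIntermeans:
    @pytest.mark.parametrize("values,expected", [
        ([0, 0, 0, 10, 10], 5.0),    # T0=4 -> class means 0,10 -> T1=5, stable
        ([1, 2, 9, 10], 5.5),        # T0=5.5 -> means 1.5, 9.5 -> stable
    ])
    def test_hand_iterated_fixed_points(self, values, expected):
        t, degenerate = intermeans_threshold(grid([values]))
        assert t == pytest.approx(expected)
        assert not degenerate

    def test_constant_image_degenerate(self):
        t, degenerate = intermeans_threshold(grid(np.zeros((5, 5))))
        assert t == 0.0 and degenerate

    def test_threshold_separates_classes(self, rng):
        vals = np.concatenate([rng.uniform(0, 0.1, 200), rng.uniform(0.8, 1.0, 50)])
        t, _ = intermeans_threshold(grid(vals.reshape(10, 25)))
        assert 0.1 < t < 0.8


class TestPreprocess:
    def test_strict_less_than_rule(self):
        out = preprocess_doppler(grid([[4, 5, 6]]), threshold=5)
        assert out.intensities.tolist() == [[0, 5, 6]]

    def test_all_zero_passthrough(self):
        out = preprocess_doppler(grid(np.zeros((4, 4))))
        assert not out.intensities.any()

    def test_no_values_in_gap(self, rng):
        img = grid(rng.uniform(0, 1, (32, 32)))
        t, _ = intermeans_threshold(img)
        out = preprocess_doppler(img, t).intensities
        assert not np.any((out > 0) & (out < t))


# -------------------------------------------------------------- clustering

def dbscan_oracle(points: np.ndarray, R: float, M: int) -> list[frozenset]:
    """Brute-force density connectivity: BFS over the <=R adjacency graph,
    keeping components with at least M points."""
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    adj = d2 <= R * R
    seen = np.zeros(n, bool)
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in np.nonzero(adj[j] & ~seen)[0]:
                seen[k] = True
                stack.append(int(k))
        if len(comp) >= M:
            comps.append(frozenset(map(tuple, points[comp].astype(int))))
    return comps


class TestClusterDoppler:
    def test_two_blocks_two_full_clusters(self):
        img = np.zeros((40, 90))
        img[5:17, 5:17] = 1.0
        img[5:17, 67:79] = 1.0  # 50 px horizontal gap
        out = cluster_doppler(grid(img), DbscanParams(R=6, M=100))
        assert [len(c) for c in out] == [144, 144]

    def test_below_minimum_size_all_noise(self, rng):
        img = np.zeros((30, 30))
        idx = rng.choice(900, size=50, replace=False)
        img[np.unravel_index(idx, img.shape)] = 1.0
        assert cluster_doppler(grid(img), DbscanParams(R=6, M=100)) == []

    def test_single_block_one_cluster(self):
        img = np.zeros((40, 40))
        img[10:30, 10:30] = 1.0
        out = cluster_doppler(grid(img), DbscanParams(R=6, M=100))
        assert len(out) == 1 and len(out[0]) == 400

    @pytest.mark.parametrize("R,M,seed", [(2.0, 5, 0), (3.5, 10, 1), (6.0, 30, 2)])
    def test_matches_brute_force_oracle(self, R, M, seed):
        rng = np.random.default_rng(seed)
        img = np.zeros((48, 48))
        for _ in range(6):  # scattered blobs of varying size
            r0, c0 = rng.integers(4, 44, 2)
            rad = rng.integers(2, 6)
            rr, cc = disk((r0, c0), rad, shape=img.shape)
            img[rr, cc] = 1.0
        out = cluster_doppler(grid(img), DbscanParams(R=R, M=M))
        got = {frozenset(map(tuple, c.member_pixels)) for c in out}
        pts = np.column_stack(np.nonzero(img)).astype(float)
        assert got == set(dbscan_oracle(pts, R, M))


# --------------------------------------------------------- Radon detection

def radon_oracle(img: np.ndarray, angles: np.ndarray) -> LineEstimate:
    """Exhaustive (theta, rho) line-integral maximization by dense bilinear
    sampling along each candidate line; ties toward smallest theta, rho."""
    from scipy.ndimage import map_coordinates

    h, w = img.shape
    cr, cc = h // 2, w // 2
    half_diag = math.hypot(h, w) / 2.0
    rho_max = int(math.ceil(half_diag))
    step = 0.25
    ts = np.arange(-half_diag, half_diag + step, step)
    best = None
    for theta in angles:
        th = math.radians(theta)
        # line: x cos + y sin = rho, x = col - cc, y = cr - row
        dx, dy = -math.sin(th), math.cos(th)  # direction in (x, y)
        for rho in range(-rho_max, rho_max + 1):
            x = rho * math.cos(th) + ts * dx
            y = rho * math.sin(th) + ts * dy
            rows, cols = cr - y, cc + x
            vals = map_coordinates(img, np.stack([rows, cols]), order=1,
                                   mode="constant", cval=0.0)
            score = vals.sum() * step
            if best is None or score > best[0] + 1e-9:
                best = (score, theta, rho)
    _, theta, rho = best
    return LineEstimate.from_theta_rho(theta, rho, img.shape)


class TestRadonLineDetect:
    def test_single_horizontal_row(self):
        img = np.zeros((41, 41))
        img[13, :] = 1.0
        line = radon_line_detect(grid(img))
        assert line.direction == pytest.approx((0.0, 1.0))
        assert line.distance_to((13, 20)) < 0.5

    def test_rotation_by_90_degrees(self):
        img = np.zeros((41, 41))
        img[13, :] = 1.0
        rot = np.rot90(img)  # horizontal row 13 -> vertical column 13
        line = radon_line_detect(grid(rot))
        assert line.angle_deg == pytest.approx(90.0)
        assert line.distance_to((20, 13)) < 0.5

    def test_longer_line_wins(self):
        img = np.zeros((64, 64))
        rr, cc = draw_line(10, 10, 31, 31)  # 30-px run at 45 degrees
        img[rr, cc] = 1.0
        rr, cc = draw_line(45, 10, 45, 19)  # 10-px horizontal run
        img[rr, cc] = 1.0
        line = radon_line_detect(grid(img))
        assert line.distance_to((10, 10)) < 1.5
        assert line.distance_to((31, 31)) < 1.5
        oracle = radon_oracle(img, np.arange(0.0, 180.0))
        assert abs(line.angle_deg - oracle.angle_deg) <= 1.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="no line"):
            radon_line_detect(grid(np.zeros((16, 16))))

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = np.zeros((48, 48))
        r0, c0 = rng.integers(5, 20, 2)
        r1, c1 = rng.integers(28, 43, 2)
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        img[rr, cc] = 1.0
        img += 0.05 * rng.uniform(size=img.shape)  # weak clutter
        angles = np.arange(0.0, 180.0, 1.0)
        line = radon_line_detect(grid(img), angles)
        oracle = radon_oracle(img, angles)
        dtheta = abs(line.angle_deg - oracle.angle_deg) % 180.0
        assert min(dtheta, 180.0 - dtheta) <= 1.0
        # the two peak lines coincide within discretization
        mid = oracle.point
        assert line.distance_to(mid) <= 1.5


class TestInitialAxis:
    def test_diagonal_strip(self):
        img = np.zeros((64, 64))
        for i in range(8, 56):
            img[i, i] = 1.0
        clusters = cluster_doppler(grid(img), DbscanParams(R=2, M=10))
        axis = initial_axis(clusters, img.shape)
        assert abs(axis.angle_deg - 45.0) <= 1.0

    def test_two_disjoint_collinear_clusters(self):
        img = np.zeros((64, 64))
        img[20:24, 5:15] = 1.0
        img[20:24, 45:55] = 1.0
        clusters = cluster_doppler(grid(img), DbscanParams(R=2, M=20))
        assert len(clusters) == 2
        axis = initial_axis(clusters, img.shape)
        for cl in clusters:
            centroid = cl.member_pixels.mean(axis=0)
            assert axis.distance_to(tuple(centroid)) < 2.0

    def test_empty_clusters_raise(self):
        with pytest.raises(ValueError, match="no Doppler evidence"):
            initial_axis([], (32, 32))


# ----------------------------------------------------------- ellipse ROIs

def cluster_from_mask(mask: np.ndarray) -> PixelCluster:
    return PixelCluster(member_pixels=np.column_stack(np.nonzero(mask)), label=0)


class TestFitEllipse:
    def test_filled_disc(self):
        img = np.zeros((41, 41), bool)
        rr, cc = disk((20, 20), 10.0)
        img[rr, cc] = True
        e = fit_ellipse(cluster_from_mask(img))
        assert e.center == pytest.approx((20, 20), abs=0.01)
        assert e.major_axis_length == pytest.approx(20.0, rel=0.05)
        assert e.minor_axis_length == pytest.approx(20.0, rel=0.05)

    def test_horizontal_strip_moments(self):
        # 41 unit-spaced points: variance (41^2-1)/12 = 140, axis 4*sqrt(140)
        img = np.zeros((5, 41), bool)
        img[2, :] = True
        e = fit_ellipse(cluster_from_mask(img))
        assert e.orientation == pytest.approx(0.0)
        assert e.major_axis_length == pytest.approx(4 * math.sqrt(140), rel=1e-9)
        assert e.minor_axis_length == 1.0  # collinear floor

    def test_translation_equivariance(self, rng):
        pts = rng.integers(0, 15, size=(60, 2))
        e1 = fit_ellipse(PixelCluster(member_pixels=pts, label=0))
        e2 = fit_ellipse(PixelCluster(member_pixels=pts + [5, 7], label=0))
        assert e2.center == pytest.approx((e1.center[0] + 5, e1.center[1] + 7))
        assert e2.major_axis_length == pytest.approx(e1.major_axis_length)
        assert e2.minor_axis_length == pytest.approx(e1.minor_axis_length)
        assert e2.orientation == pytest.approx(e1.orientation)

    def test_rotation_equivariance_within_discretization(self):
        # an elongated strip rotated 30 degrees: orientation tracks within 2
        # degrees and axis lengths within 5%
        base = np.zeros((81, 81), bool)
        base[38:43, 10:71] = True
        e0 = fit_ellipse(cluster_from_mask(base))
        ang = math.radians(30.0)
        pts = np.column_stack(np.nonzero(base)).astype(float) - 40.0
        rot = np.column_stack([
            pts[:, 0] * math.cos(ang) + pts[:, 1] * math.sin(ang),
            -pts[:, 0] * math.sin(ang) + pts[:, 1] * math.cos(ang)]) + 40.0
        e1 = fit_ellipse(PixelCluster(member_pixels=np.round(rot).astype(int), label=0))
        delta = abs(e1.orientation - (e0.orientation + 30.0)) % 180.0
        assert min(delta, 180.0 - delta) <= 2.0
        assert e1.major_axis_length == pytest.approx(e0.major_axis_length, rel=0.05)


class TestFilterRois:
    axis = LineEstimate(point=(20, 0), direction=(0, 1))  # horizontal, row 20

    def circle(self, row, radius=5.0):
        return EllipseROI(center=(row, 50), major_axis_length=2 * radius,
                          minor_axis_length=2 * radius)

    def test_centered_on_line_retained(self):
        assert filter_rois([self.circle(20)], self.axis) != []

    def test_far_from_line_removed(self):
        assert filter_rois([self.circle(40)], self.axis) == []

    def test_tangency_counts(self):
        assert filter_rois([self.circle(25)], self.axis) != []   # distance == radius
        assert filter_rois([self.circle(25.01)], self.axis) == []

    def test_oriented_ellipse_support(self):
        # semi-axes (10, 2) at 0 degrees: vertical support is 2 px
        e = EllipseROI(center=(22, 50), major_axis_length=20,
                       minor_axis_length=4, orientation=0.0)
        assert filter_rois([e], self.axis) == [e]  # distance 2 == support
        e_far = EllipseROI(center=(23, 50), major_axis_length=20,
                           minor_axis_length=4, orientation=0.0)
        assert filter_rois([e_far], self.axis) == []
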