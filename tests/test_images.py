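"""TIC normalization, ion-image extraction, and display thresholding."""

import numpy as np
import pytest

from oculims.images import (
    apply_intensity_threshold,
    compute_tic,
    extract_ion_image,
    image_to_array,
)
from oculims.imzml import MSIDataset, Spectrum
from oculims.masses import MassWindow
from oculims.phantom import LABELS


def dataset_of(rows, mz_range=(200.0, 310.0)):
    """rows: {coord: (mz list, intensity list)}"""
    return MSIDataset(
        {c: Spectrum(mz, it) for c, (mz, it) in rows.items()}, mz_range=mz_range
    )


class TestTIC:
    def test_sums_intensities(self):
        ds = dataset_of({(1, 1): ([250.0, 260.0], [3.0, 1.0]), (2, 1): ([], [])})
        tic = compute_tic(ds)
        assert tic[(1, 1)] == 4.0
        assert tic[(2, 1)] == 0.0

    def test_respects_range(self):
        ds = dataset_of({(1, 1): ([250.0, 260.0, 300.0], [3.0, 1.0, 5.0])})
        assert compute_tic(ds, mz_range=(255.0, 310.0))[(1, 1)] == 6.0

    def test_matches_phantom_ground_truth(self, small_quiet_phantom):
        ds, gt = small_quiet_phantom
        tic = compute_tic(ds)
        expected = gt.noiseless_tic()
        for (x, y), value in tic.items():
            assert value == pytest.approx(expected[y - 1, x - 1], rel=1e-6)


class TestExtraction:
    def test_peak_at_center(self):
        ds = dataset_of({(1, 1): ([290.17507], [42.0])})
        img = extract_ion_image(ds, MassWindow(290.17507, 0.0009))
        assert img.values[(1, 1)] == 42.0
        assert not img.normalized

    def test_half_width_boundary_excludes(self):
        """A peak 0.0005 Da off-center is outside a 0.0009-Da full-width window."""
        ds = dataset_of({(1, 1): ([290.17507 + 0.0005], [42.0])})
        img = extract_ion_image(ds, MassWindow(290.17507, 0.0009))
        assert img.values[(1, 1)] == 0.0

    def test_window_outside_range_rejected(self):
        ds = dataset_of({(1, 1): ([250.0], [1.0])})
        with pytest.raises(ValueError):
            extract_ion_image(ds, MassWindow(150.0, 0.0009))

    def test_normalized_bounds_and_zero_tic_flagging(self):
        ds = dataset_of(
            {(1, 1): ([250.0, 290.0], [1.0, 3.0]), (2, 1): ([], [])}
        )
        tic = compute_tic(ds)
        img = extract_ion_image(ds, MassWindow(290.0, 0.001), tic)
        assert img.normalized
        assert img.values[(1, 1)] == pytest.approx(0.75)
        assert img.values[(2, 1)] == 0.0
        assert (2, 1) in img.zero_tic_pixels
        # value 1 only when the window holds the pixel's entire signal
        only = dataset_of({(1, 1): ([290.0], [5.0])})
        img2 = extract_ion_image(only, MassWindow(290.0, 0.001), compute_tic(only))
        assert img2.values[(1, 1)] == 1.0

    def test_linearity_in_intensities(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(200, 310, 6))
        it = rng.uniform(0, 10, 6)
        window = MassWindow(float(mz[2]), 5.0)
        v1 = extract_ion_image(dataset_of({(1, 1): (mz, it)}), window).values[(1, 1)]
        v3 = extract_ion_image(dataset_of({(1, 1): (mz, 3 * it)}), window).values[(1, 1)]
        assert v3 == pytest.approx(3 * v1, rel=1e-6)

    def test_disjoint_windows_conserve_normalized_total(self):
        """Windows tiling the mass range sum to 1 for every pixel with TIC > 0."""
        rng = np.random.default_rng(1)
        ds = dataset_of(
            {
                (x, 1): (np.sort(rng.uniform(201, 309, 5)), rng.uniform(1, 9, 5))
                for x in range(1, 5)
            }
        )
        tic = compute_tic(ds)
        edges = np.linspace(200.0, 310.0, 12)  # peak-free boundaries (random draws)
        totals = {c: 0.0 for c in ds.spectra}
        for lo, hi in zip(edges[:-1], edges[1:]):
            img = extract_ion_image(
                ds, MassWindow((lo + hi) / 2, hi - lo), tic
            )
            for c, v in img.values.items():
                totals[c] += v
        for c, total in totals.items():
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_phantom_extraction_correlates_with_ground_truth(self, small_config):
        import dataclasses

        from oculims.phantom import generate_phantom

        # drift off: extraction from uncalibrated drifting spectra is exactly
        # what the lock-mass stage exists to fix (tested in test_pipeline)
        cfg = dataclasses.replace(small_config, mass_drift_sigma_da=0.0)
        ds, gt = generate_phantom(cfg)  # default intensity noise levels
        img = extract_ion_image(ds, MassWindow(cfg.target_mz, 0.0009))
        pairs = np.array(
            [(v, gt.field[y - 1, x - 1]) for (x, y), v in img.values.items()]
        )
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert r >= 0.95


class TestThreshold:
    def test_full_scale_is_pure_rescale(self):
        img = extract_ion_image(
            dataset_of({(1, 1): ([250.0], [2.0]), (2, 1): ([250.0], [8.0])}),
            MassWindow(250.0, 1.0),
        )
        disp = apply_intensity_threshold(img, 1.0, relative=True)
        assert disp.values[(1, 1)] == pytest.approx(0.25)
        assert disp.values[(2, 1)] == 1.0

    def test_half_max_saturates(self):
        img = extract_ion_image(
            dataset_of({(1, 1): ([250.0], [2.0]), (2, 1): ([250.0], [8.0])}),
            MassWindow(250.0, 1.0),
        )
        disp = apply_intensity_threshold(img, 0.5, relative=True)
        assert disp.values[(1, 1)] == pytest.approx(0.5)
        assert disp.values[(2, 1)] == 1.0

    def test_lowering_threshold_never_darkens(self):
        rng = np.random.default_rng(2)
        ds = dataset_of(
            {(x, 1): ([250.0], [float(rng.uniform(0, 10))]) for x in range(1, 9)}
        )
        img = extract_ion_image(ds, MassWindow(250.0, 1.0))
        hi = apply_intensity_threshold(img, 0.9, relative=True)
        lo = apply_intensity_threshold(img, 0.3, relative=True)
        for c in img.values:
            assert lo.values[c] >= hi.values[c] - 1e-12

    def test_nonpositive_threshold_rejected(self):
        img = extract_ion_image(
            dataset_of({(1, 1): ([250.0], [2.0])}), MassWindow(250.0, 1.0)
        )
        with pytest.raises(ValueError):
            apply_intensity_threshold(img, 0.0)

    def test_posterior_contrast_reveals_sclera_not_lens(self, small_quiet_phantom):
        """Low full-intensity threshold lights up weak scleral signal while the
        lens and vitreous stay at exactly zero (no drug there)."""
        ds, gt = small_quiet_phantom
        from oculims.images import compute_tic as tic_fn

        img = extract_ion_image(
            ds, MassWindow(gt.config.target_mz, 0.0009), tic_fn(ds)
        )
        full = apply_intensity_threshold(img, 1.0, relative=True)
        low = apply_intensity_threshold(img, 0.05, relative=True)

        def by_label(disp, *names):
            codes = {LABELS[n] for n in names}
            return np.array(
                [
                    v
                    for (x, y), v in disp.values.items()
                    if gt.labels[y - 1, x - 1] in codes
                ]
            )

        sclera_full = by_label(full, "sclera")
        sclera_low = by_label(low, "sclera")
        dark_low = by_label(low, "lens", "vitreous")
        assert sclera_low.min() > 0.0  # drug reaches the whole sclera
        assert np.median(sclera_low) > np.median(sclera_full)  # contrast boost
        assert dark_low.max() == 0.0  # lens/vitreous carry no signal


def test_image_to_array_layout():
    img = extract_ion_image(
        dataset_of({(2, 1): ([250.0], [5.0]), (1, 3): ([250.0], [7.0])}),
        MassWindow(250.0, 1.0),
    )
    arr = image_to_array(img, fill=0.0)
    assert arr.shape == (3, 2)
    assert arr[0, 1] == 5.0 and arr[2, 0] == 7.0
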