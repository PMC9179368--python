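"""The ppm-axis convention and lossless spectrum/cohort round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsidh.spectra_io import (
    AcquisitionParams,
    Cohort,
    InvalidParameterError,
    Spectrum,
    SpectrumFormatError,
    ppm_axis,
    read_cohort,
    read_spectrum,
    write_cohort,
    write_spectrum,
)


class TestPpmAxis:
    def test_derived_transmitter_frequency(self):
        assert AcquisitionParams(1.5, 1000, 1024).transmitter_frequency_mhz == pytest.approx(63.864)
        assert AcquisitionParams(3.0, 1200, 1024).transmitter_frequency_mhz == pytest.approx(127.728)

    def test_original_regime_axis(self):
        # hand oracle: span = 1200 / 127.728 = 9.3945.. ppm; top endpoint at
        # center + span/2, bottom one step above center - span/2
        axis = ppm_axis(AcquisitionParams(3.0, 1200, 1024))
        span = 1200 / 127.728
        assert axis.span == pytest.approx(span)
        assert axis.values[0] == pytest.approx(4.7 + span / 2)  # 9.3975
        assert axis.values[-1] == pytest.approx(0.0117, abs=5e-4)
        assert len(axis) == 1024

    def test_validation_regime_axis(self):
        axis = ppm_axis(AcquisitionParams(1.5, 1000, 1024))
        assert axis.span == pytest.approx(1000 / 63.864)  # 15.658 ppm
        assert axis.spacing == pytest.approx(0.015291, abs=1e-6)

    def test_two_point_axis_spans_one_ppm(self):
        # SW numerically equal to f0 (in MHz x 1e6 scaled units) -> 1.0 ppm
        params = AcquisitionParams(
            3.0, 127.728, 2, transmitter_frequency_mhz=127.728
        )
        axis = ppm_axis(params)
        assert axis.span == pytest.approx(1.0)
        assert axis.values[0] - axis.values[1] == pytest.approx(0.5)

    def test_span_ratio_between_regimes_is_five_thirds(self):
        a15 = ppm_axis(AcquisitionParams(1.5, 1000, 1024))
        a30 = ppm_axis(AcquisitionParams(3.0, 1200, 1024))
        assert a15.span / a30.span == pytest.approx(5 / 3)

    @given(
        field=st.floats(0.5, 10),
        sw=st.floats(100, 5000),
        n=st.integers(2, 4096),
    )
    @settings(max_examples=50, deadline=None)
    def test_axis_is_exact_uniform_decreasing_map(self, field, sw, n):
        axis = ppm_axis(AcquisitionParams(field, sw, n))
        diffs = np.diff(axis.values)
        assert np.all(diffs < 0)
        assert np.allclose(diffs, diffs[0], rtol=0, atol=1e-12)
        assert len(axis) == n

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(field_strength_t=-1.0, spectral_width_hz=1000, n_points=16),
            dict(field_strength_t=1.5, spectral_width_hz=0, n_points=16),
            dict(field_strength_t=1.5, spectral_width_hz=1000, n_points=1),
            dict(
                field_strength_t=1.5,
                spectral_width_hz=1000,
                n_points=16,
                transmitter_frequency_mhz=-5,
            ),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            AcquisitionParams(**kwargs)


class TestSpectrumFiles:
    @given(
        intensities=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False, width=64), min_size=4, max_size=64
        ),
        field=st.floats(0.5, 7),
        sw=st.floats(100, 3000),
    )
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_is_lossless(self, tmp_path_factory, intensities, field, sw):
        params = AcquisitionParams(field, sw, len(intensities), echo_time_ms=30.0)
        spec = Spectrum(np.array(intensities), params, id="rt", label="MUT")
        path = tmp_path_factory.mktemp("rt") / "s.tsv"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        assert np.array_equal(back.intensities, spec.intensities)
        assert back.params == spec.params
        assert back.id == "rt" and back.label == "mut"

    def test_length_mismatch_is_an_error(self, tmp_path):
        params = AcquisitionParams(3.0, 1200, 8)
        spec = Spectrum(np.zeros(8), params, id="x")
        path = tmp_path / "s.tsv"
        write_spectrum(spec, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-2]) + "\n")  # drop two intensity rows
        with pytest.raises(SpectrumFormatError, match="n_points"):
            read_spectrum(path)

    def test_missing_spectral_width_names_the_key(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("#field_strength_T\t3.0\n#n_points\t2\n0.0\n1.0\n")
        with pytest.raises(SpectrumFormatError, match="spectral_width_Hz"):
            read_spectrum(path)

    def test_unparsable_intensity_names_the_line(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "#field_strength_T\t3.0\n#spectral_width_Hz\t1200\n#n_points\t2\n"
            "0.5\nbogus\n"
        )
        with pytest.raises(SpectrumFormatError, match="5"):
            read_spectrum(path)

    def test_wrong_length_at_construction(self):
        params = AcquisitionParams(3.0, 1200, 1024)
        with pytest.raises(SpectrumFormatError, match="1000"):
            Spectrum(np.zeros(1000), params)


class TestCohorts:
    def _cohort(self, n=3):
        params = AcquisitionParams(3.0, 1200, 16)
        rng = np.random.default_rng(1)
        labels = ["mut", "wt", "unknown"]
        return Cohort(
            [
                Spectrum(rng.normal(size=16), params, id=f"s{i}", label=labels[i % 3])
                for i in range(n)
            ],
            name="toy",
        )

    def test_roundtrip_preserves_order_and_labels(self, tmp_path):
        cohort = self._cohort()
        manifest = write_cohort(cohort, tmp_path)
        back = read_cohort(manifest)
        assert len(back) == 3
        assert back.exclusion_ledger == {}
        assert [s.id for s in back] == [s.id for s in cohort]
        for a, b in zip(back, cohort):
            assert np.array_equal(a.intensities, b.intensities)
            assert a.label == b.label

    def test_manifest_labels_parsed_case_insensitively(self, tmp_path):
        cohort = self._cohort()
        manifest = write_cohort(cohort, tmp_path)
        text = manifest.read_text().replace("\tmut", "\tMuT").replace("\twt", "\tWT")
        manifest.write_text(text)
        back = read_cohort(manifest)
        assert back.labels() == ["mut", "wt", "unknown"]

    def test_duplicate_ids_rejected(self, tmp_path):
        cohort = self._cohort()
        manifest = write_cohort(cohort, tmp_path)
        text = manifest.read_text().replace("s1", "s0")
        manifest.write_text(text)
        with pytest.raises(SpectrumFormatError, match="duplicate"):
            read_cohort(manifest)

    def test_missing_member_file_rejected(self, tmp_path):
        cohort = self._cohort()
        manifest = write_cohort(cohort, tmp_path)
        (tmp_path / "s1.tsv").unlink()
        with pytest.raises(SpectrumFormatError, match="s1"):
            read_cohort(manifest)
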