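import itertools

import numpy as np
import pytest

from peptwin.chem import PeptideIon, precursor_mz
from peptwin.prediction import (
    FallbackPredictor,
    KYTE_DOOLITTLE,
    KoinaClient,
    PredictionConfig,
    PredictionError,
    filter_relative_intensity,
    top_n_peaks,
)
from peptwin.spectra import PeakList


class TestFallbackSpectra:
    def test_peptide_ladder_shape(self):
        spec = FallbackPredictor().predict_spectrum(PeptideIon("PEPTIDE", 2))
        assert len(spec.peaks) == 12  # 2 x (7 - 1)
        # most intense peak is y6 at 1.0
        top = np.argmax(spec.peaks.intensity)
        assert spec.peaks.intensity[top] == pytest.approx(1.0)
        y6 = max(
            f_mz for f_mz, inten in zip(spec.peaks.mz, spec.peaks.intensity)
            if inten == spec.peaks.intensity[top]
        )
        assert spec.peaks.mz[top] == pytest.approx(y6)

    def test_deterministic_bit_identical(self):
        fp = FallbackPredictor()
        s1 = fp.predict_spectrum(PeptideIon("ELVISLIVESK", 2))
        s2 = fp.predict_spectrum(PeptideIon("ELVISLIVESK", 2))
        assert s1.peaks == s2.peaks
        assert s1.retention == s2.retention

    def test_permutations_share_precursor_but_not_fragments(self):
        a = FallbackPredictor().predict_spectrum(PeptideIon("ACDEFK", 2))
        b = FallbackPredictor().predict_spectrum(PeptideIon("CADEFK", 2))
        assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-9)
        assert set(np.round(a.peaks.mz, 6)) != set(np.round(b.peaks.mz, 6))

    def test_length_one_rejected(self):
        with pytest.raises(PredictionError):
            FallbackPredictor().predict_spectrum(PeptideIon("G", 1))


class TestFallbackIrt:
    def test_dialanine_reference(self):
        assert FallbackPredictor.irt("AA") == pytest.approx(3.6)

    def test_permutation_invariant(self):
        values = {FallbackPredictor.irt("".join(p)) for p in itertools.permutations("ACDEF")}
        assert len({round(v, 9) for v in values}) == 1

    def test_homopolymer_magnitude_grows(self):
        assert abs(FallbackPredictor.irt("IIII")) > abs(FallbackPredictor.irt("III"))
        assert abs(FallbackPredictor.irt("RRRR")) > abs(FallbackPredictor.irt("RRR"))

    def test_covers_all_residues(self):
        assert sorted(KYTE_DOOLITTLE) == sorted("ACDEFGHIKLMNPQRSTVWY")


class TestTopNPeaks:
    def test_selection_keeps_most_intense(self, rng):
        peaks = PeakList(np.sort(rng.uniform(100, 1000, 12)), rng.uniform(0, 1, 12))
        out = top_n_peaks(peaks, 5)
        assert len(out) == 5
        dropped = set(np.round(peaks.mz, 9)) - set(np.round(out.mz, 9))
        kept_min = out.intensity.min()
        for mz in dropped:
            idx = np.argmin(np.abs(peaks.mz - mz))
            assert peaks.intensity[idx] <= kept_min

    def test_n_at_least_count_is_identity(self):
        peaks = PeakList([100.0, 200.0], [0.5, 1.0])
        assert top_n_peaks(peaks, 5) == peaks

    def test_tie_at_cutoff_keeps_lower_mz(self):
        peaks = PeakList([100.0, 200.0, 300.0], [1.0, 0.5, 0.5])
        out = top_n_peaks(peaks, 2)
        assert list(out.mz) == [100.0, 200.0]

    def test_idempotent(self, rng):
        peaks = PeakList(np.sort(rng.uniform(100, 1000, 20)), rng.uniform(0, 1, 20))
        once = top_n_peaks(peaks, 7)
        assert top_n_peaks(once, 7) == once

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            top_n_peaks(PeakList([100.0], [1.0]), 0)


class TestRelativeIntensityFilter:
    def test_threshold(self):
        peaks = PeakList([100.0, 200.0, 300.0], [1.0, 0.5, 0.04])
        assert len(filter_relative_intensity(peaks, 0.05)) == 2

    def test_fraction_one_keeps_only_base_peak(self):
        peaks = PeakList([100.0, 200.0], [0.3, 1.0])
        out = filter_relative_intensity(peaks, 1.0)
        assert list(out.mz) == [200.0]

    def test_single_peak_unchanged(self):
        peaks = PeakList([100.0], [0.2])
        assert filter_relative_intensity(peaks, 0.99) == peaks

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            filter_relative_intensity(PeakList([100.0], [1.0]), fraction)

    def test_idempotent(self, rng):
        peaks = PeakList(np.sort(rng.uniform(100, 1000, 20)), rng.uniform(0, 1, 20))
        once = filter_relative_intensity(peaks, 0.1)
        assert filter_relative_intensity(once, 0.1) == once


# ---------------------------------------------------------------------------
# Remote client driven through a synthetic recorded-response stub
# ---------------------------------------------------------------------------

class StubTransport:
    """Offline stand-in for the inference service: answers with fallback
    b/y ladders padded by -1 placeholders, mimicking the response schema."""

    def __init__(self, fail_times: int = 0, drop_last: bool = False):
        self.requests: list[tuple[str, dict]] = []
        self.fail_times = fail_times
        self.drop_last = drop_last

    def __call__(self, url: str, payload: dict) -> dict:
        if self.fail_times > 0:
            self.fail_times -= 1
            raise OSError("synthetic network failure")
        self.requests.append((url, payload))
        inputs = {i["name"]: i["data"] for i in payload["inputs"]}
        sequences = inputs["peptide_sequences"]
        if "/infer" not in url:
            raise ValueError(f"unexpected url {url}")
        if url.rsplit("/", 2)[-2].endswith("_irt") or "irt" in url.lower():
            data = [FallbackPredictor.irt(s) for s in sequences]
            return {"outputs": [
                {"name": "irt", "datatype": "FP32", "shape": [len(data), 1], "data": data}
            ]}
        charges = inputs["precursor_charges"]
        width = 0
        rows = []
        for seq, z in zip(sequences, charges):
            spec = FallbackPredictor().predict_spectrum(PeptideIon(seq, int(z)))
            rows.append((list(spec.peaks.mz), list(spec.peaks.intensity)))
            width = max(width, len(rows[-1][0]))
        if self.drop_last:
            rows = rows[:-1]
        mz_flat, int_flat = [], []
        for mzs, ints in rows:
            pad = width - len(mzs)
            mz_flat.extend(mzs + [-1.0] * pad)
            int_flat.extend(ints + [-1.0] * pad)
        shape = [len(rows), width]
        return {"outputs": [
            {"name": "mz", "datatype": "FP32", "shape": shape, "data": mz_flat},
            {"name": "intensities", "datatype": "FP32", "shape": shape, "data": int_flat},
            {"name": "annotation", "datatype": "BYTES", "shape": shape, "data": []},
        ]}


class TestKoinaClient:
    def test_stub_round_trip_produces_valid_records(self):
        client = KoinaClient(transport=StubTransport())
        ions = [PeptideIon("PEPTIDEK", 2), PeptideIon("ELVISLIVESK", 3)]
        records = client.predict_spectra(ions)
        assert [r.name for r in records] == ["PEPTIDEK/2", "ELVISLIVESK/3"]
        for ion, rec in zip(ions, records):
            assert rec.precursor_mz == pytest.approx(precursor_mz(ion))
            assert np.all(np.diff(rec.peaks.mz) > 0)
            assert np.all(rec.peaks.intensity > 0)  # placeholders dropped
            assert rec.retention_kind == "irt"

    def test_empty_batch_sends_no_request(self):
        stub = StubTransport()
        client = KoinaClient(transport=stub)
        assert client.predict_spectra([]) == []
        assert stub.requests == []

    def test_short_response_is_contract_violation(self):
        client = KoinaClient(transport=StubTransport(drop_last=True))
        ions = [PeptideIon("PEPTIDEK", 2), PeptideIon("ELVISLIVESK", 3)]
        with pytest.raises(PredictionError, match="1 spectra"):
            client.predict_spectra(ions)

    def test_network_failure_raises_after_retries(self):
        client = KoinaClient(transport=StubTransport(fail_times=10), retries=2)
        with pytest.raises(PredictionError, match="after 2 attempts"):
            client.predict_irt([PeptideIon("PEPTIDEK", 2)])

    def test_transient_failure_retried(self):
        client = KoinaClient(transport=StubTransport(fail_times=1), retries=2)
        irts = client.predict_irt([PeptideIon("AA", 2)])
        assert irts == [pytest.approx(3.6)]

    def test_batching_respects_batch_size(self):
        stub = StubTransport()
        client = KoinaClient(transport=stub)
        ions = [PeptideIon("PEPTIDEK", 2)] * 5
        client.predict_irt(ions, PredictionConfig(batch_size=2))
        assert len(stub.requests) == 3
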