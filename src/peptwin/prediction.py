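"""Fragment-intensity and iRT prediction behind a pluggable contract.

Two predictors implement the contract:

* :class:`KoinaClient` — a thin HTTP client for a Koina-style inference
  service (model name, peptide sequences, charges, NCE).  It is optional:
  the package never needs the network, and tests drive the client through a
  recorded-response stub transport.
* :class:`FallbackPredictor` — a deterministic offline stand-in.  Its
  intensity rule (a linear ramp over fragment ordinals) is intentionally
  simple and exists to exercise matching, grouping and scoring; it is NOT a
  model of HCD fragmentation chemistry and must never be mistaken for one.
  Its iRT is the Kyte–Doolittle hydropathy sum of the sequence — additive,
  so sequence permutations share an iRT exactly, the way near-isobaric
  permuted peptides co-elute in the scenarios this tool quantifies.

Spectrum post-processing (top-n peaks, relative-intensity floor) lives here
too, since it is applied to predictions before scoring.
"""

from __future__ import annotations

import json
import logging
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .chem import PeptideIon, precursor_mz, theoretical_fragments
from .spectra import PeakList, SpectrumRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionConfig",
    "Predictor",
    "PredictionError",
    "FallbackPredictor",
    "KoinaClient",
    "KYTE_DOOLITTLE",
    "top_n_peaks",
    "filter_relative_intensity",
]


#: Kyte–Doolittle hydropathy coefficients, the fallback iRT scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PredictionConfig:
    """Prediction parameters.  NCE 30 and the 2020 HCD intensity model are
    the usual tryptic-proteomics setup."""

    collision_energy: float = 30.0
    intensity_model: str = "Prosit_2020_intensity_HCD"
    irt_model: str = "Prosit_2019_irt"
    batch_size: int = 1000

    def __post_init__(self) -> None:
        if self.collision_energy <= 0:
            raise ValueError("collision energy must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


class PredictionError(RuntimeError):
    """A predictor failed or violated its contract."""


class Predictor(Protocol):
    """What every predictor must provide: spectra and iRT values aligned
    1:1 with the input ions, order preserved."""

    def predict_spectra(
        self, ions: Sequence[PeptideIon], config: PredictionConfig
    ) -> list[SpectrumRecord]: ...

    def predict_irt(
        self, ions: Sequence[PeptideIon], config: PredictionConfig
    ) -> list[float]: ...


# ---------------------------------------------------------------------------
# Deterministic offline fallback
# ---------------------------------------------------------------------------

class FallbackPredictor:
    """Pure-function predictor: singly-charged b/y ladders with a linear
    intensity ramp, and additive Kyte–Doolittle iRT."""

    def predict_spectra(
        self, ions: Sequence[PeptideIon], config: PredictionConfig = PredictionConfig()
    ) -> list[SpectrumRecord]:
        return [self.predict_spectrum(ion, config) for ion in ions]

    def predict_spectrum(
        self, ion: PeptideIon, config: PredictionConfig = PredictionConfig()
    ) -> SpectrumRecord:
        """y_i gets intensity i/(n−1), b_i half that, then the spectrum is
        rescaled to base peak 1.0.  Fully deterministic."""
        n = len(ion.sequence)
        if n < 2:
            raise PredictionError(f"cannot predict a spectrum for {ion.sequence!r}: length < 2")
        frags = theoretical_fragments(ion, ("b", "y"), max_fragment_charge=1)
        mz = [f.mz for f in frags]
        inten = [
            (f.ordinal / (n - 1)) * (0.5 if f.series == "b" else 1.0) for f in frags
        ]
        peaks = PeakList(mz, inten).scaled(1.0)
        return SpectrumRecord(
            name=ion.identifier,
            sequence=ion.sequence,
            charge=ion.charge,
            precursor_mz=precursor_mz(ion),
            retention=self.irt(ion.sequence),
            retention_kind="irt",
            peaks=peaks,
        )

    @staticmethod
    def irt(sequence: str) -> float:
        return float(sum(KYTE_DOOLITTLE[ch] for ch in sequence))

    def predict_irt(
        self, ions: Sequence[PeptideIon], config: PredictionConfig = PredictionConfig()
    ) -> list[float]:
        return [self.irt(ion.sequence) for ion in ions]


# ---------------------------------------------------------------------------
# Remote (Koina-style) client
# ---------------------------------------------------------------------------

#: transport(url, payload_dict) -> response_dict; injectable for offline tests.
Transport = Callable[[str, dict], dict]


def _urllib_transport(url: str, payload: dict) -> dict:
    data = json.dumps(payload).encode()
    req = urllib.request.Request(
        url, data=data, headers={"Content-Type": "application/json"}
    )
    with urllib.request.urlopen(req, timeout=60) as resp:
        return json.loads(resp.read().decode())


class KoinaClient:
    """Batched client for a Koina-style triton inference endpoint.

    Requests carry ``peptide_sequences``, ``precursor_charges`` and
    ``collision_energies`` inputs; responses are expected to provide
    ``mz``, ``intensities`` (and ``annotation``) outputs per batch, shaped
    (batch, n_fragments).  Negative or placeholder (-1) intensities, which
    the services use to pad impossible fragments, are dropped from peak
    lists.  All network failures surface as :class:`PredictionError` after
    ``retries`` attempts.
    """

    def __init__(
        self,
        endpoint: str = "https://koina.wilhelmlab.org:443",
        transport: Optional[Transport] = None,
        retries: int = 2,
    ):
        self.endpoint = endpoint.rstrip("/")
        self.transport = transport or _urllib_transport
        self.retries = retries

    def _infer(self, model: str, inputs: list[dict]) -> dict:
        url = f"{self.endpoint}/v2/models/{model}/infer"
        payload = {"id": "0", "inputs": inputs}
        last: Optional[Exception] = None
        for attempt in range(1, self.retries + 1):
            try:
                return self.transport(url, payload)
            except (urllib.error.URLError, OSError, ValueError) as exc:
                last = exc
                logger.warning("request to %s failed (attempt %d/%d): %s",
                               url, attempt, self.retries, exc)
        raise PredictionError(
            f"model {model!r} at {self.endpoint} unreachable after "
            f"{self.retries} attempts: {last}"
        )

    @staticmethod
    def _batches(ions: Sequence[PeptideIon], size: int):
        for start in range(0, len(ions), size):
            yield ions[start : start + size]

    @staticmethod
    def _str_input(name: str, values: list[str]) -> dict:
        return {"name": name, "datatype": "BYTES",
                "shape": [len(values), 1], "data": values}

    @staticmethod
    def _num_input(name: str, values: list, datatype: str = "FP32") -> dict:
        return {"name": name, "datatype": datatype,
                "shape": [len(values), 1], "data": values}

    @staticmethod
    def _output(response: dict, name: str) -> dict:
        for out in response.get("outputs", []):
            if out["name"] == name:
                return out
        raise PredictionError(f"response missing output {name!r}")

    def predict_spectra(
        self, ions: Sequence[PeptideIon], config: PredictionConfig = PredictionConfig()
    ) -> list[SpectrumRecord]:
        records: list[SpectrumRecord] = []
        if not ions:
            return records
        irts = self.predict_irt(ions, config)
        for batch in self._batches(ions, config.batch_size):
            response = self._infer(
                config.intensity_model,
                [
                    self._str_input("peptide_sequences", [i.sequence for i in batch]),
                    self._num_input("precursor_charges", [i.charge for i in batch], "INT32"),
                    self._num_input(
                        "collision_energies",
                        [config.collision_energy] * len(batch),
                    ),
                ],
            )
            mz_out = self._output(response, "mz")
            int_out = self._output(response, "intensities")
            n_rows = mz_out["shape"][0]
            if n_rows != len(batch):
                raise PredictionError(
                    f"model {config.intensity_model!r} returned {n_rows} spectra "
                    f"for {len(batch)} ions"
                )
            width = mz_out["shape"][1]
            mz_arr = np.asarray(mz_out["data"], dtype=float).reshape(n_rows, width)
            int_arr = np.asarray(int_out["data"], dtype=float).reshape(n_rows, width)
            for ion, row_mz, row_int in zip(batch, mz_arr, int_arr):
                keep = (row_int > 0) & (row_mz > 0)
                records.append(
                    SpectrumRecord(
                        name=ion.identifier,
                        sequence=ion.sequence,
                        charge=ion.charge,
                        precursor_mz=precursor_mz(ion),
                        peaks=PeakList(row_mz[keep], row_int[keep]),
                    )
                )
        for rec, irt in zip(records, irts):
            rec.retention = irt
            rec.retention_kind = "irt"
        return records

    def predict_irt(
        self, ions: Sequence[PeptideIon], config: PredictionConfig = PredictionConfig()
    ) -> list[float]:
        if not ions:
            return []
        irts: list[float] = []
        for batch in self._batches(ions, config.batch_size):
            response = self._infer(
                config.irt_model,
                [self._str_input("peptide_sequences", [i.sequence for i in batch])],
            )
            out = self._output(response, "irt")
            data = list(np.asarray(out["data"], dtype=float).ravel())
            if len(data) != len(batch):
                raise PredictionError(
                    f"model {config.irt_model!r} returned {len(data)} iRT values "
                    f"for {len(batch)} ions"
                )
            irts.extend(data)
        return irts


# ---------------------------------------------------------------------------
# Spectrum post-processing
# ---------------------------------------------------------------------------

def top_n_peaks(peaks: PeakList, n: int) -> PeakList:
    """Keep the ``n`` most intense peaks (ties broken toward lower m/z),
    re-sorted by m/z.  Idempotent for fixed n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if len(peaks) <= n:
        return peaks
    # stable sort on (-intensity, mz): equal intensities keep the lower m/z
    order = sorted(range(len(peaks)), key=lambda k: (-peaks.intensity[k], peaks.mz[k]))
    keep = sorted(order[:n])
    return PeakList(peaks.mz[keep], peaks.intensity[keep])


def filter_relative_intensity(peaks: PeakList, fraction: float) -> PeakList:
    """Keep peaks with intensity ≥ fraction × base-peak intensity."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(peaks) == 0:
        return peaks
    threshold = fraction * peaks.base_peak_intensity()
    keep = peaks.intensity >= threshold
    return PeakList(peaks.mz[keep], peaks.intensity[keep])
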