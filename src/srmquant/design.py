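"""Serial-dilution SRM experimental design.

The design emulated here is a serial two-fold dilution of a spiked serum
pool: 6 samples (the pure pool plus 5 dilutions of the spiked parent
solution), each sampled as 4 aliquots read over 4 couples of days, with
2 separate digestions per aliquot and 2 injections per digestion.  In
addition, daily quality-control (QC) readings of a sample of known
concentration (2 vials x 2 injections per day) calibrate the digestion
yield four times per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["DesignSpec", "InvalidDesignError", "build_design", "design_counts"]


class InvalidDesignError(ValueError):
    """Raised when a design specification violates its invariants."""


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the serial-dilution SRM experiment.

    Defaults reproduce the reference design: 6 samples (pool + 5 two-fold
    dilutions), 4 aliquots per sample (one per day-couple), 2 digestions
    per aliquot, 2 injections per digestion, and 2 QC vials x 2 injections
    per reading day (4 digestion-yield calibrations per day).
    """

    n_dilutions: int = 5
    dilution_base: float = 0.5
    include_pool: bool = True
    aliquots_per_sample: int = 4
    digestions_per_aliquot: int = 2
    injections_per_digestion: int = 2
    n_day_couples: int = 4
    qc_vials_per_day: int = 2
    qc_injections_per_vial: int = 2
    qc_dilution_step: int = 2  # QC aliquots come from dilution 1/4
    days_per_couple: int = 2
    elisa_replicates_per_sample: int = 5
    elisa_reads_per_replicate: int = 4

    def __post_init__(self) -> None:
        counts = (
            self.n_dilutions,
            self.aliquots_per_sample,
            self.digestions_per_aliquot,
            self.injections_per_digestion,
            self.n_day_couples,
            self.qc_vials_per_day,
            self.qc_injections_per_vial,
            self.days_per_couple,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise InvalidDesignError(f"all design counts must be integers >= 1, got {counts}")
        if not 0.0 < self.dilution_base < 1.0:
            raise InvalidDesignError(
                f"dilution_base must lie in (0, 1), got {self.dilution_base}"
            )

    @property
    def n_samples(self) -> int:
        return self.n_dilutions + int(self.include_pool)

    @property
    def readings_per_sample(self) -> int:
        """SRM readings of one sample (classical quantifier view)."""
        return (
            self.aliquots_per_sample
            * self.digestions_per_aliquot
            * self.injections_per_digestion
        )

    @property
    def yield_calibrations_per_day(self) -> int:
        return self.qc_vials_per_day * self.qc_injections_per_vial

    @property
    def elisa_readings_per_sample(self) -> int:
        return self.elisa_replicates_per_sample * self.elisa_reads_per_replicate


def build_design(spec: DesignSpec) -> pd.DataFrame:
    """Deterministically enumerate the design table.

    Returns a DataFrame with one row per SRM reading:

    ``reading_id, sample_id, dilution, day_couple, day, aliquot, digestion,
    injection, is_qc``

    Sample ``k`` (k = 0 .. n_dilutions-1) has theoretical dilution
    ``dilution_base ** k``; the serum pool carries no defined spike dilution
    (``dilution`` is NaN).  Each aliquot of a sample maps to exactly one
    day-couple; digestion ``d`` of an aliquot is read on day ``d`` of that
    couple.  QC rows (vials of the QC dilution) are enumerated per day.
    """
    if not isinstance(spec, DesignSpec):
        spec = DesignSpec(**spec)  # accept a mapping for convenience

    rows: list[dict] = []
    samples: list[tuple[str, float]] = []
    if spec.include_pool:
        samples.append(("pool", float("nan")))
    for k in range(spec.n_dilutions):
        samples.append((f"dil_{k}", spec.dilution_base**k))

    for sample_id, dilution in samples:
        for aliquot in range(1, spec.aliquots_per_sample + 1):
            # one aliquot per day-couple, cycling if aliquots exceed couples
            day_couple = (aliquot - 1) % spec.n_day_couples + 1
            for digestion in range(1, spec.digestions_per_aliquot + 1):
                day = (digestion - 1) % spec.days_per_couple + 1
                for injection in range(1, spec.injections_per_digestion + 1):
                    rows.append(
                        {
                            "reading_id": (
                                f"{sample_id}-a{aliquot}-d{digestion}-i{injection}"
                            ),
                            "sample_id": sample_id,
                            "dilution": dilution,
                            "day_couple": day_couple,
                            "day": day,
                            "aliquot": aliquot,
                            "digestion": digestion,
                            "injection": injection,
                            "is_qc": False,
                        }
                    )

    qc_dilution = spec.dilution_base**spec.qc_dilution_step
    for day_couple in range(1, spec.n_day_couples + 1):
        for day in range(1, spec.days_per_couple + 1):
            for vial in range(1, spec.qc_vials_per_day + 1):
                for injection in range(1, spec.qc_injections_per_vial + 1):
                    rows.append(
                        {
                            "reading_id": (
                                f"qc-c{day_couple}-y{day}-v{vial}-i{injection}"
                            ),
                            "sample_id": "qc",
                            "dilution": qc_dilution,
                            "day_couple": day_couple,
                            "day": day,
                            "aliquot": vial,
                            "digestion": vial,
                            "injection": injection,
                            "is_qc": True,
                        }
                    )

    table = pd.DataFrame(rows)
    if table["reading_id"].duplicated().any():
        raise InvalidDesignError("reading ids are not unique")  # pragma: no cover
    return table


def design_counts(spec: DesignSpec) -> dict[str, int]:
    """Headline counts of the design, as reported for the reference layout.

    The classical quantifier sees 16 readings/sample; the Bayesian
    quantifier re-estimates every reading once per digestion-yield
    calibration of its reading day, hence readings/sample x calibrations/day.
    """
    return {
        "n_samples": spec.n_samples,
        "srm_aliquots": spec.n_samples * spec.aliquots_per_sample,
        "nlp_readings_per_sample": spec.readings_per_sample,
        "bhi_readings_per_sample": spec.readings_per_sample
        * spec.yield_calibrations_per_day,
        "yield_calibrations_per_day": spec.yield_calibrations_per_day,
        "elisa_readings_per_sample": spec.elisa_readings_per_sample,
    }
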