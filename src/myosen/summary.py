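"""Per-biopsy summary variables.

One :class:`SampleSummary` holds the within-participant values of every
senescence and morphology variable the pipeline produces for one muscle
section: the p16 focus percentages, TAF percentages, HMGB1 / Lamin B1
positivity percentages, and the four morphology metrics.  Fields that a
given marker panel cannot produce are ``None`` (missing), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict


_PCT_FIELDS = (
    "pct_p16_nuclei_2plus",
    "pct_p16_fibre_2plus",
    "pct_p16_any_2plus",
    "pct_taf_2plus",
    "pct_taf_3plus",
    "pct_hmgb1_pos",
    "pct_laminb1_pos",
    "taf_pct_of_gh2ax",
    "fibrotic_area_pct",
    "cnf_pct",
)


@dataclass
class SampleSummary:
    """Variable set summarising one biopsy section.

    Percentages are on the 0-100 scale.  ``min_feret_mean`` is in µm when a
    pixel size is known and in arbitrary units otherwise (``feret_units``).
    ``flags`` collects QC annotations such as ``low_n`` (denominator below
    the configured analysis window).
    """

    pct_p16_nuclei_2plus: float | None = None
    pct_p16_fibre_2plus: float | None = None
    pct_p16_any_2plus: float | None = None
    pct_taf_2plus: float | None = None
    pct_taf_3plus: float | None = None
    pct_hmgb1_pos: float | None = None
    pct_laminb1_pos: float | None = None
    taf_pct_of_gh2ax: float | None = None
    min_feret_mean: float | None = None
    feret_units: str = "um"
    fibre_number: float | None = None
    fibrotic_area_pct: float | None = None
    cnf_pct: float | None = None
    n_nuclei_analysed: int | None = None
    n_fibres_analysed: int | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v!r} outside [0, 100]")
        t2, t3 = self.pct_taf_2plus, self.pct_taf_3plus
        if t2 is not None and t3 is not None and t3 > t2 + 1e-9:
            raise ValueError("pct_taf_3plus cannot exceed pct_taf_2plus")

    def to_dict(self) -> dict:
        return asdict(self)

    def filled_fields(self) -> list[str]:
        """Names of non-missing numeric fields."""
        out = []
        for f in fields(self):
            if f.name in ("flags", "feret_units"):
                continue
            if getattr(self, f.name) is not None:
                out.append(f.name)
        return out
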