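"""smFISH quantification and ChIP-qPCR percent-input.

smFISH: single-molecule spots are calibrated by the median integrated
intensity of non-transcription-site spots (the unit intensity of one RNA
molecule); each bright nuclear spot is assigned a nascent-RNA count by
rounding its intensity ratio, and nuclear spots carrying three or more
molecule-equivalents are transcription sites (TS).  Cells are classified as
No / Mono / Bi-allelic by their TS count.

ChIP-qPCR: percent input is computed from Ct values with the 20%-input
dilution constant folded into the exponent,
``%input = 2**((Ct_input - 5.64) - Ct_sample) * 100``; fold enrichment
normalizes %input to a reference primer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SmFishCellRecord",
    "quantify_smfish",
    "chip_percent_input",
]

TS_MIN_MOLECULES = 3          # nuclear spot with >= 3 molecule-equivalents is a TS
MIN_CALIBRATION_SPOTS = 20
CHIP_INPUT_CONSTANT = 5.64    # encodes the 20% input fraction and dilution


@dataclass(frozen=True)
class SmFishCellRecord:
    """Per-cell smFISH quantification."""

    cell_id: int
    mrna_count: int                       # single-molecule (non-TS) spots, molecule-weighted
    nuclear_count: int                    # molecules inside the nucleus excluding TS
    cytoplasmic_count: int
    transcription_sites: tuple = field(default_factory=tuple)  # ((y, x, nascent), ...)
    allele_class: str = "No"              # "No" | "Mono" | "Bi"
    flagged: bool = False                 # > 2 transcription sites

    def __post_init__(self) -> None:
        for _, _, nascent in self.transcription_sites:
            if nascent < TS_MIN_MOLECULES:
                raise ValueError("every transcription site must carry >= 3 molecules")
        n_ts = len(self.transcription_sites)
        expect = {0: "No", 1: "Mono", 2: "Bi"}.get(n_ts)
        if expect is not None and self.allele_class != expect:
            raise ValueError("allele class inconsistent with TS count")


def _allele_class(n_ts: int) -> tuple[str, bool]:
    if n_ts == 0:
        return "No", False
    if n_ts == 1:
        return "Mono", False
    if n_ts == 2:
        return "Bi", False
    return "Bi", True  # more than two TS: flagged, reported as Bi


def quantify_smfish(
    spots: pd.DataFrame,
    unit_intensity: float | None = None,
    background: float = 0.0,
) -> list[SmFishCellRecord]:
    """Quantify smFISH spots into per-cell mRNA counts, TS and allele classes.

    ``spots`` needs columns ``cell_id``, ``y_px``, ``x_px``,
    ``integrated_intensity`` and boolean ``in_nucleus``.  Unless given, the
    unit (single-molecule) intensity is calibrated image-wide as the median
    integrated intensity of spots that are not TS candidates; at least 20
    such spots are required.  ``background`` is subtracted from integrated
    intensities before ratioing (default on, pass 0 to disable).

    Molecule counts are the intensity ratio rounded to the nearest integer
    (minimum 1 per detected spot); nuclear spots with a rounded count >= 3
    are transcription sites and contribute their nascent count separately
    from the mRNA count.
    """
    required = {"cell_id", "y_px", "x_px", "integrated_intensity", "in_nucleus"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spots table missing columns: {sorted(missing)}")
    inten = spots["integrated_intensity"].to_numpy(dtype=float) - background
    if unit_intensity is None:
        # first pass: anything below 2x the global median is a single-molecule candidate
        med = float(np.median(inten))
        singles = inten[inten < 2.0 * med]
        if singles.size < MIN_CALIBRATION_SPOTS:
            raise ValueError(
                f"too few calibration spots ({singles.size} < {MIN_CALIBRATION_SPOTS})"
            )
        unit_intensity = float(np.median(singles))
    if unit_intensity <= 0:
        raise ValueError("unit intensity must be > 0")

    molecules = np.maximum(np.rint(inten / unit_intensity).astype(int), 1)
    df = spots.assign(_molecules=molecules)
    records = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        ts = []
        mrna = nuc = cyto = 0
        for _, row in grp.iterrows():
            m = int(row["_molecules"])
            if row["in_nucleus"] and m >= TS_MIN_MOLECULES:
                ts.append((float(row["y_px"]), float(row["x_px"]), m))
            elif row["in_nucleus"]:
                nuc += m
                mrna += m
            else:
                cyto += m
                mrna += m
        cls, flagged = _allele_class(len(ts))
        records.append(
            SmFishCellRecord(
                cell_id=int(cell_id), mrna_count=mrna, nuclear_count=nuc,
                cytoplasmic_count=cyto, transcription_sites=tuple(ts),
                allele_class=cls, flagged=flagged,
            )
        )
    return records


def smfish_table(records: list[SmFishCellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cell_id": r.cell_id, "mrna_count": r.mrna_count,
             "nuclear_count": r.nuclear_count, "cytoplasmic_count": r.cytoplasmic_count,
             "n_ts": len(r.transcription_sites),
             "nascent_counts": ";".join(str(t[2]) for t in r.transcription_sites),
             "allele_class": r.allele_class, "flagged": r.flagged}
            for r in records
        ]
    )


def chip_percent_input(
    ct_input: float,
    ct_sample: float,
    ct_reference_pair: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """ChIP-qPCR percent input, and fold enrichment over a reference locus.

    ``%input = 2**((Ct_input - 5.64) - Ct_sample) * 100``.  When
    ``ct_reference_pair = (ct_input_ref, ct_sample_ref)`` is given, fold
    enrichment is %input / %input(reference); otherwise NaN.
    """
    for v in (ct_input, ct_sample):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    pct = 2.0 ** ((ct_input - CHIP_INPUT_CONSTANT) - ct_sample) * 100.0
    fold = np.nan
    if ct_reference_pair is not None:
        ref_pct, _ = chip_percent_input(*ct_reference_pair)
        fold = pct / ref_pct
    return pct, fold
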