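"""State-specific open-chromatin derivation from replicate ATAC peak sets.

Reproducibility is replicate-anchored: the reference replicate's peaks
that overlap the other replicate are kept with their original
boundaries (no merging or clipping). State-specific sets are whole-peak
set differences between the two common sets; "shared" regions are the
common-diagnosis peaks that overlap common-relapse, reported with the
diagnosis side's coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .intervals import PeakSet, overlap_pairs, subtract, write_bed

__all__ = ["StatePeaks", "common_peaks", "derive_states"]


def common_peaks(a: PeakSet, b: PeakSet) -> PeakSet:
    """Peaks of reference replicate ``a`` with >=1 overlapping peak in ``b``."""
    hit = {i for i, _ in overlap_pairs(a.intervals, b.intervals)}
    return PeakSet(a.sample_id, [iv for i, iv in enumerate(a.intervals) if i in hit])


@dataclass
class StatePeaks:
    """Common and state-specific reproducible peak sets."""

    common_diagnosis: PeakSet
    common_relapse: PeakSet
    diagnosis_specific: PeakSet
    relapse_specific: PeakSet
    shared: PeakSet

    def counts(self) -> dict[str, int]:
        return {
            "common_diagnosis": len(self.common_diagnosis),
            "common_relapse": len(self.common_relapse),
            "diagnosis_specific": len(self.diagnosis_specific),
            "relapse_specific": len(self.relapse_specific),
            "shared": len(self.shared),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "common_diagnosis",
            "common_relapse",
            "diagnosis_specific",
            "relapse_specific",
            "shared",
        ):
            write_bed(getattr(self, name), out / f"{name}.bed")
        meta = dict(self.counts())
        meta["shared_coordinates_from"] = "diagnosis"
        with open(out / "summary.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def derive_states(
    d1: PeakSet, d2: PeakSet, r1: PeakSet, r2: PeakSet
) -> StatePeaks:
    """Derive common and state-specific peaks from a 2+2 replicate design.

    common_diagnosis = d1 peaks overlapping d2 (d1 is the reference
    replicate; likewise r1 for relapse). Shared regions are common
    diagnosis peaks overlapping the common relapse set; each specific set
    removes, as whole peaks, anything overlapping the other state's
    common set, so the two specific sets can never overlap each other.
    """
    cd = common_peaks(d1, d2)
    cr = common_peaks(r1, r2)
    shared_idx = {i for i, _ in overlap_pairs(cd.intervals, cr.intervals)}
    shared = PeakSet(
        "shared", [iv for i, iv in enumerate(cd.intervals) if i in shared_idx]
    )
    diagnosis_specific = subtract(cd, cr)
    relapse_specific = subtract(cr, cd)
    diagnosis_specific.sample_id = "diagnosis_specific"
    relapse_specific.sample_id = "relapse_specific"
    return StatePeaks(
        common_diagnosis=cd,
        common_relapse=cr,
        diagnosis_specific=diagnosis_specific,
        relapse_specific=relapse_specific,
        shared=shared,
    )
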