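"""Reading and writing the pipeline's file formats.

Sections are OME-TIFF (channels named "DAPI", "WGA", marker names, or a
single "RGB" plane for brightfield); ground truth goes to JSON plus a
label-raster TIFF; section specifications round-trip through YAML; object
tables (nuclei, fibres, foci, per-sample summaries) are CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .summary import SampleSummary
from .synthetic import GroundTruth, SectionImage, SectionSpec


def write_section(img: SectionImage, path) -> None:
    path = Path(path)
    if img.modality == "brightfield":
        tifffile.imwrite(path, img.pixels, photometric="rgb",
                         metadata={"axes": "YXS"})
        return
    axes = "ZCYX" if img.pixels.ndim == 4 else "CYX"
    tifffile.imwrite(
        path, img.pixels, metadata={
            "axes": axes,
            "Channel": {"Name": list(img.channels)},
            "PhysicalSizeX": img.pixel_size_um,
            "PhysicalSizeY": img.pixel_size_um,
        }, ome=True)


def read_section(path, pixel_size_um: float = 1.0) -> SectionImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        names = None
        if tf.ome_metadata:
            import re
            names = re.findall(r'Channel[^>]*Name="([^"]+)"', tf.ome_metadata)
    if arr.ndim == 3 and arr.shape[-1] == 3 and arr.dtype == np.uint8:
        return SectionImage(arr, ("RGB",), "brightfield", pixel_size_um)
    channels = tuple(names) if names else tuple(
        f"ch{i}" for i in range(arr.shape[-3]))
    return SectionImage(arr, channels, "fluorescence", pixel_size_um)


def spec_to_yaml(spec: SectionSpec, path) -> None:
    d = dataclasses.asdict(spec)
    d["field_size_px"] = list(d["field_size_px"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def spec_from_yaml(path) -> SectionSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["field_size_px"] = tuple(d["field_size_px"])
    return SectionSpec(**d)


def write_ground_truth(gt: GroundTruth, json_path, labels_path=None) -> None:
    d = {
        "fibre_polygons": [p.tolist() for p in gt.fibre_polygons],
        "fibre_edge": [bool(e) for e in gt.fibre_edge],
        "fibre_central": [bool(c) for c in gt.fibre_central],
        "nuclei": [{"center": list(n.center), "axes": list(n.axes),
                    "angle": n.angle, "class": n.cls, "fibre_id": n.fibre_id,
                    "z_center": n.z_center}
                   for n in gt.nuclei],
        "nucleus_marker_class": gt.nucleus_marker_class,
        "foci_true": {ch: [dataclasses.asdict(f) for f in foci]
                      for ch, foci in gt.foci_true.items()},
        "p16_extranuclear": {str(k): v for k, v in gt.p16_extranuclear.items()},
        "fibrotic_area_pct": 100.0 * float(gt.fibrotic_mask.mean()),
        "per_sample_truth": gt.per_sample_truth.to_dict(),
    }
    Path(json_path).write_text(json.dumps(d))
    if labels_path is not None:
        tifffile.imwrite(labels_path, gt.fibre_labels.astype(np.int32))


def nuclei_to_csv(nuclei, path) -> None:
    rows = [{"nucleus_id": n.nucleus_id, "x": n.centroid[0], "y": n.centroid[1],
             "area_px": n.area_px, "is_myonuclear": n.is_myonuclear,
             "fibre_id": n.fibre_id, "qc_excluded": n.qc_excluded,
             "qc_reason": n.qc_reason, "taf_count": n.taf_count,
             "ring_integrated_density": n.ring_integrated_density,
             **{f"mean_{k}": v for k, v in n.mean_intensity.items()}}
            for n in nuclei]
    pd.DataFrame(rows).to_csv(path, index=False)


def fibres_to_csv(fibres, path) -> None:
    rows = [{"fibre_id": f.fibre_id, "area_px": f.area_px,
             "csa_um2": f.csa_um2, "min_feret_um": f.min_feret_um,
             "min_feret_au": f.min_feret_au, "edge": f.edge,
             "central_nucleus": f.central_nucleus,
             "p16_foci_nuclear": f.p16_foci_nuclear,
             "p16_foci_extranuclear": f.p16_foci_extranuclear,
             "n_nuclei": len(f.nucleus_ids)}
            for f in fibres]
    pd.DataFrame(rows).to_csv(path, index=False)


def foci_to_csv(foci_sets: dict, path) -> None:
    rows = []
    for name, fs in foci_sets.items():
        for i in range(len(fs)):
            row = {"channel": name, "x": fs.points[i, 0], "y": fs.points[i, 1]}
            if fs.points.shape[1] == 3:
                row["z"] = fs.points[i, 2]
            row["intensity"] = fs.intensities[i]
            if fs.nucleus_assignment is not None:
                row["nucleus_id"] = int(fs.nucleus_assignment[i])
            if fs.fibre_assignment is not None:
                row["fibre_id"] = int(fs.fibre_assignment[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def append_sample_summary(summary: SampleSummary, participant_id: str,
                          panel: str, path) -> None:
    """Append one per-sample row to a cohort-level CSV keyed by
    participant and marker panel."""
    path = Path(path)
    row = {"participant_id": participant_id, "panel": panel,
           **{k: v for k, v in summary.to_dict().items() if k != "flags"},
           "flags": ";".join(summary.flags)}
    df = pd.DataFrame([row])
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


def write_provenance(path, **kwargs) -> None:
    """JSON sidecar echoing thresholds and denominators used for a run."""
    Path(path).write_text(json.dumps(kwargs, indent=2, default=str))
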