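"""End-to-end orchestration: stack -> preprocessing -> surface -> peaks.

Stage order: channel unmixing, bright
outlier removal, validity masking, half-maximum surface extraction,
reference-polynomial fit, penetration map (smoothing + mode zeroing),
negative-peak detection, prominence computation, histograms, summary.
Every run writes a metadata JSON echoing all parameters (defaults
included) and per-stage input/output hashes so reordering is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import GelpenError
from .preprocess import MixingMatrix, make_validity_mask, remove_outliers, unmix_channels
from .stack_io import MultiChannelStack, read_stack, write_peaks_table, write_plane_tiff
from .summarize import MigrationSummary, compare_conditions, summarize_peaks
from .surface import (
    DepthMap,
    PenetrationMap,
    SurfaceModel,
    compute_penetration,
    extract_surface,
    fit_reference_surface,
)
from .topography import PeakSet, compute_prominences, detect_negative_peaks, histogram_values

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_EMPTY_MASK = 3


class RunConfig(BaseModel):
    """All pipeline parameters and their defaults.

    The polynomial degree is fixed at 3 and the in-plane connectivity at
    8; both are echoed in run metadata, and overriding the degree logs a
    warning.
    """

    input: Optional[str] = None
    output_dir: str = "out"
    gel_channel: int | str = 0
    cell_channel: int | str = 1
    mixing_matrix: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    outlier_radius_px: int = Field(2, ge=1)
    outlier_threshold: float = Field(50.0, ge=0.0)
    outlier_threshold_is_8bit: bool = True  # scale by data max / 255 when data exceeds 8-bit range
    snr_floor: float = Field(3.0, ge=0.0)
    erode_border_px: int = Field(8, ge=0)
    presmooth_sigma_px: float = Field(1.0, ge=0.0)
    polynomial_degree: int = 3
    sigma_um: float = Field(2.0, ge=0.0)
    bin_um: float = Field(1.0, gt=0.0)
    h_floor_um: float = Field(5.0, gt=0.0)
    connectivity: int = 8
    cell_type: str = ""
    day: str = ""
    gel_type: str = ""
    seed: int = 0  # phantom mode only

    @field_validator("polynomial_degree")
    @classmethod
    def _check_degree(cls, v: int) -> int:
        if v != 3:
            logger.warning("polynomial_degree=%d requested; the reference basis is fixed at 3", v)
            raise ValueError("only total degree 3 is supported for the reference surface")
        return v

    @field_validator("connectivity")
    @classmethod
    def _check_conn(cls, v: int) -> int:
        if v != 8:
            raise ValueError("in-plane connectivity is fixed at 8")
        return v


@dataclass
class PipelineResult:
    """In-memory artifacts of one analysis run."""

    depth: DepthMap
    model: SurfaceModel
    penetration: PenetrationMap
    peaks: PeakSet
    summary: MigrationSummary
    stage_hashes: dict[str, str]


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def analyze_stack(stack: MultiChannelStack, config: RunConfig) -> PipelineResult:
    """Run the analysis stages on an in-memory stack."""
    hashes: dict[str, str] = {"input_gel": _hash_array(stack.gel), "input_cell": _hash_array(stack.cell)}

    mix = MixingMatrix(config.mixing_matrix)
    unmixed = unmix_channels(stack, mix)
    hashes["unmixed_gel"] = _hash_array(unmixed.gel)

    gel = np.asarray(unmixed.gel, dtype=np.float32)
    threshold = config.outlier_threshold
    data_max = float(gel.max()) if gel.size else 0.0
    if config.outlier_threshold_is_8bit and data_max > 255.0:
        threshold = threshold * data_max / 255.0
    clean = remove_outliers(gel, config.outlier_radius_px, threshold)
    hashes["outliers_removed"] = _hash_array(clean)

    valid = make_validity_mask(clean, config.snr_floor, config.erode_border_px)
    hashes["validity_mask"] = _hash_array(valid.mask)

    depth = extract_surface(clean, stack.geometry, valid, config.presmooth_sigma_px)
    hashes["depth_map"] = _hash_array(np.nan_to_num(depth.z_um))

    model = fit_reference_surface(depth)
    hashes["surface_model"] = _hash_array(model.coeffs)

    pen = compute_penetration(depth, model, sigma_um=config.sigma_um, bin_um=config.bin_um)
    hashes["penetration_map"] = _hash_array(np.nan_to_num(pen.value_um))

    peaks = detect_negative_peaks(pen, config.h_floor_um)
    peaks = compute_prominences(pen, peaks)
    hashes["peaks"] = hashlib.sha256(
        repr([(p.y_px, p.x_px, p.depth_um, p.prominence_um) for p in peaks.ordered()]).encode()
    ).hexdigest()[:16]

    labels = {"cell_type": config.cell_type, "day": config.day, "gel_type": config.gel_type}
    summary = summarize_peaks(peaks, labels)
    return PipelineResult(
        depth=depth, model=model, penetration=pen, peaks=peaks, summary=summary, stage_hashes=hashes
    )


def run_pipeline(
    config: RunConfig, stack: MultiChannelStack | None = None
) -> dict:
    """Full run with artifact writing; returns the manifest.

    Artifacts (in ``config.output_dir``): depth_map.tif, penetration.tif,
    peaks.csv, histograms.csv, summary.csv, run_metadata.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_hash = None
    if stack is None:
        if config.input is None:
            raise GelpenError("run_pipeline needs an input path or an in-memory stack")
        input_hash = _hash_file(Path(config.input))
        stack = read_stack(config.input, role_map={"gel": _key(config.gel_channel), "cell": _key(config.cell_channel)})

    result = analyze_stack(stack, config)

    artifacts: dict[str, str] = {}

    p = out / "depth_map.tif"
    write_plane_tiff(np.nan_to_num(result.depth.z_um, nan=-1.0), p)
    artifacts["depth_map"] = p.name

    p = out / "penetration.tif"
    write_plane_tiff(np.nan_to_num(result.penetration.value_um, nan=0.0), p)
    artifacts["penetration"] = p.name

    p = out / "peaks.csv"
    write_peaks_table(result.peaks, p)
    artifacts["peaks"] = p.name

    p = out / "histograms.csv"
    _write_histograms(result, config.bin_um, p)
    artifacts["histograms"] = p.name

    p = out / "summary.csv"
    compare_conditions([result.summary]).to_csv(p, index=False, lineterminator="\n")
    artifacts["summary"] = p.name

    manifest = {
        "gelpen_version": __version__,
        "parameters": json.loads(config.model_dump_json()),
        "input_sha256_16": input_hash,
        "stage_hashes": result.stage_hashes,
        "surface_model": result.model.to_dict(),
        "mode_shift_um": result.penetration.mode_shift_um,
        "n_peaks": len(result.peaks),
        "artifacts": artifacts,
    }
    p = out / "run_metadata.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["artifacts"]["run_metadata"] = p.name
    return manifest


def _key(v: int | str) -> int | str:
    try:
        return int(v)
    except (TypeError, ValueError):
        return v


def _write_histograms(result: PipelineResult, bin_um: float, path: Path) -> None:
    import pandas as pd

    rows = []
    pen_valid = result.penetration.value_um[result.penetration.valid.mask]
    for quantity, values in (
        ("peak_depth_um", result.peaks.depths_um),
        ("peak_prominence_um", result.peaks.prominences_um),
        ("penetration_um", pen_valid),
    ):
        h = histogram_values(values, bin_um)
        for i in range(h.n_bins):
            rows.append(
                {
                    "quantity": quantity,
                    "bin_left_um": h.bin_edges_um[i],
                    "bin_right_um": h.bin_edges_um[i + 1],
                    "count": int(h.counts[i]),
                }
            )
    pd.DataFrame(rows, columns=["quantity", "bin_left_um", "bin_right_um", "count"]).to_csv(
        path, index=False, lineterminator="\n"
    )
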