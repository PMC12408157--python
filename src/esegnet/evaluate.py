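"""Directory-level evaluation: match predicted and reference masks by case
stem, compute per-case metric reports and write CSV/JSON summaries."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from PIL import Image

from . import io as eio
from .metrics import (MetricReport, aggregate_reports, evaluate_case,
                      write_report_csv, write_report_json)

__all__ = ["collect_masks", "evaluate_dirs"]

_MASK_SUFFIXES = (".png", ".nii", ".nii.gz")


def _stem(path: Path) -> str:
    name = path.name
    for suf in (".nii.gz", ".nii", ".png"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    for tag in ("_pred", "_mask"):
        if name.endswith(tag):
            name = name[: -len(tag)]
    return name


def collect_masks(directory) -> Dict[str, Path]:
    out = {}
    for p in sorted(Path(directory).iterdir()):
        if p.name.endswith(_MASK_SUFFIXES) and "_img" not in p.name:
            out[_stem(p)] = p
    return out


def _load_mask(path: Path):
    if path.name.endswith(".png"):
        return np.asarray(Image.open(path)).astype(np.int64), None
    arr, spacing = eio.read_volume(path)
    return np.asarray(arr).astype(np.int64), spacing


def evaluate_dirs(pred_dir, gt_dir, *, include_background=False,
                  out_prefix=None) -> Tuple[List[MetricReport], dict, list]:
    """Evaluate every case present in both directories.

    Returns (per-case reports, aggregate stats, unmatched case ids); when
    ``out_prefix`` is given, also writes ``<prefix>.json``/``<prefix>.csv``.
    """
    preds = collect_masks(pred_dir)
    gts = collect_masks(gt_dir)
    common = sorted(set(preds) & set(gts))
    unmatched = sorted(set(preds) ^ set(gts))
    reports = []
    for cid in common:
        pm, _ = _load_mask(preds[cid])
        gm, spacing = _load_mask(gts[cid])
        reports.append(evaluate_case(pm, gm, spacing=spacing,
                                     include_background=include_background,
                                     case_id=cid))
    agg = aggregate_reports(reports)
    if unmatched:
        agg["unmatched_cases"] = unmatched
    if out_prefix is not None:
        write_report_json(str(out_prefix) + ".json", reports)
        write_report_csv(str(out_prefix) + ".csv", reports)
    return reports, agg, unmatched
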