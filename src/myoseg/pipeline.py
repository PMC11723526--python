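"""End-to-end orchestration: from a dataset manifest (or in-memory scenes)
through segmentation and post-processing to per-image record tables and
per-group diameter / nuclei-count summaries.

Groups are free-form labels (the motivating study compares young/aged
control vs dexamethasone-treated myotube cultures, labelled Y-Con, Y-Dex,
A-Con, A-Dex); summaries report the sample mean and sample (n-1) standard
deviation of the per-image mean myotube diameter and nuclei-per-myotube
count, plus percent change against a reference group.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio, postprocess
from .model import SegOutputs, forward, load_checkpoint

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "GroupSummary", "run_pipeline", "summarize_groups", "group_ttest"]


@dataclass
class PipelineConfig:
    manifest: str | None = None  # CSV written by synthetic.generate_dataset
    out_dir: str = "myoseg_out"
    um_per_px: float = 1.0
    checkpoint: str | None = None
    use_truth_masks: bool = False
    groups: dict = field(default_factory=dict)  # scene_id -> group label
    tile_size: int = 512
    overlap: int = 0
    binarize_threshold: float = 0.5
    min_object_px: int = 25
    min_branch_px: int = postprocess.MIN_BRANCH_PX
    marker_dilation_px: int = postprocess.MARKER_DILATION_PX
    seed: int = 0

    def __post_init__(self):
        if not self.use_truth_masks and self.checkpoint is None:
            raise ValueError("provide a model checkpoint or set use_truth_masks=True")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must be in (0, 1)")

    def config_hash(self) -> str:
        """Hash of every computation-affecting field (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class GroupSummary:
    group: str
    n_images: int
    diameter_mean_um: float
    diameter_std_um: float
    nuclei_mean: float
    nuclei_std: float
    single_sample: bool = False


# ---------------------------------------------------------------------------

def _outputs_for_row(row, cfg: PipelineConfig, model) -> SegOutputs:
    if cfg.use_truth_masks:
        for key in ("path_mask_myotube", "path_mask_nuclei", "path_mask_centroid"):
            if not Path(row[key]).exists():
                raise FileNotFoundError(f"missing mask file {row[key]} for scene {row['scene_id']}")
        return SegOutputs(
            *(dataio.read_mask(row[k]).astype(np.float32)
              for k in ("path_mask_myotube", "path_mask_nuclei", "path_mask_centroid"))
        )
    img_path = Path(row["path_image"])
    if not img_path.exists():
        raise FileNotFoundError(f"missing image file {img_path} for scene {row['scene_id']}")
    raw = dataio.read_image(img_path)
    image = dataio.normalize_and_stack(raw[0], raw[1])
    c, h, w = image.shape
    size = min(cfg.tile_size, h, w)
    tiles, origins = dataio.tile_for_inference(image, size=size, overlap=cfg.overlap)
    outs = [forward(model, np.asarray(t, np.float32)) for t in tiles]
    stitched = [
        dataio.stitch([o.as_tuple()[k] for o in outs], origins, h, w) for k in range(3)
    ]
    return SegOutputs(*stitched)


def run_pipeline(cfg: PipelineConfig):
    """Process every manifest row; writes per-image record CSVs and a group
    summary table under ``cfg.out_dir``. Returns (summaries, summary_df)."""
    if cfg.manifest is None:
        raise ValueError("PipelineConfig.manifest is required")
    manifest = pd.read_csv(cfg.manifest)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = None if cfg.use_truth_masks else load_checkpoint(cfg.checkpoint)
    chash = cfg.config_hash()

    per_group: dict[str, list[dict]] = {}
    for _, row in manifest.iterrows():
        sid = row["scene_id"]
        group = cfg.groups.get(sid, cfg.groups.get(str(sid), "all"))
        outputs = _outputs_for_row(row, cfg, model)
        records = postprocess.quantify_image(
            outputs,
            um_per_px=float(row.get("um_per_px", cfg.um_per_px)),
            binarize_threshold=cfg.binarize_threshold,
            min_object_px=cfg.min_object_px,
            min_branch_px=cfg.min_branch_px,
            marker_dilation_px=cfg.marker_dilation_px,
        )
        df = postprocess.records_to_dataframe(records)
        path = out / f"records_scene_{sid:03d}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            df.to_csv(fh, index=False)
        rollups = df[df.branch_id == -1]
        per_group.setdefault(group, []).append(
            {
                "scene_id": sid,
                "diameter_um": float(rollups.diameter_um_mean.mean()) if len(rollups) else np.nan,
                "n_nuclei": float(rollups.n_nuclei.mean()) if len(rollups) else np.nan,
            }
        )

    summaries, deltas = summarize_groups(per_group)
    summary_df = pd.DataFrame([asdict(s) for s in summaries])
    with open(out / "group_summary.csv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        summary_df.to_csv(fh, index=False)
    if deltas is not None:
        with open(out / "group_deltas.csv", "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            deltas.to_csv(fh, index=False)
    return summaries, summary_df


# ---------------------------------------------------------------------------

def summarize_groups(records_by_group: dict, reference: str | None = None):
    """Sample mean / (n-1) std per group plus percent deltas vs a reference.

    ``records_by_group`` maps group label -> list of per-image records; each
    record is a dict with ``diameter_um`` and ``n_nuclei`` (plain numbers are
    accepted and treated as diameters). Returns (list[GroupSummary], deltas
    DataFrame or None if only one group).
    """
    if any(len(v) == 0 for v in records_by_group.values()):
        empty = [k for k, v in records_by_group.items() if not len(v)]
        raise ValueError(f"group(s) with no records: {empty}")
    summaries = []
    for group in records_by_group:  # insertion order is reproducible
        recs = records_by_group[group]
        diam = np.array(
            [r["diameter_um"] if isinstance(r, dict) else float(r) for r in recs], float
        )
        nuc = np.array([r.get("n_nuclei", np.nan) if isinstance(r, dict) else np.nan for r in recs])
        single = len(recs) == 1
        if single:
            logger.warning("group %r has a single record; std reported as 0", group)
        summaries.append(
            GroupSummary(
                group=str(group),
                n_images=len(recs),
                diameter_mean_um=float(np.nanmean(diam)),
                diameter_std_um=0.0 if single else float(np.nanstd(diam, ddof=1)),
                nuclei_mean=float(np.nanmean(nuc)) if not np.isnan(nuc).all() else np.nan,
                nuclei_std=(0.0 if single else float(np.nanstd(nuc, ddof=1)))
                if not np.isnan(nuc).all()
                else np.nan,
                single_sample=single,
            )
        )
    deltas = None
    if len(summaries) > 1:
        ref = next(s for s in summaries if reference is None or s.group == reference)
        rows = []
        for s in summaries:
            if s.group == ref.group:
                continue
            def pct(val, base):
                if not (np.isfinite(val) and np.isfinite(base)) or base == 0:
                    return np.nan
                return 100.0 * (val / base - 1.0)

            rows.append(
                {
                    "group": s.group,
                    "reference": ref.group,
                    "diameter_pct_change": pct(s.diameter_mean_um, ref.diameter_mean_um),
                    "nuclei_pct_change": pct(s.nuclei_mean, ref.nuclei_mean),
                }
            )
        deltas = pd.DataFrame(rows)
    return summaries, deltas


def group_ttest(a, b):
    """Convenience Welch two-sample t-test between two groups of per-image
    values. The motivating study marks significance without naming its test;
    treat this as an exploratory aid, not a replication of its statistics."""
    from scipy import stats

    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)
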