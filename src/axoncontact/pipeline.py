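"""Simulate -> quantify -> compare orchestration and group statistics.

``run_experiment`` drives a whole synthetic experiment from a config mapping
(or YAML file): generate a preset's condition pair or contact segments,
quantify every segment, compute the effect size and a group-comparison test,
and return a deterministic, provenance-stamped report.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import contact, intensity, synth
from .contact import ContactConfig
from .errors import ConfigError
from .presets import get_preset

__all__ = [
    "ComparisonReport", "run_experiment", "validate_manifest",
    "quantify_pair", "quantify_contact", "quantify_branch",
]


@dataclass(frozen=True)
class ComparisonReport:
    """Per-condition summaries plus effect size, test result and provenance."""

    preset: str
    quantifier: str
    seed: int
    config_hash: str
    n: dict[str, int]
    means: dict[str, float]
    sds: dict[str, float]
    effect_name: str
    effect_value: float
    test_name: str
    p_value: float
    extras: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _band_width_px(segment: synth.SimulatedSegment) -> int:
    w = segment.scene.trace.width_nm / segment.image.pixel_size_nm
    return int(math.ceil(w)) + 2


def quantify_pair(pair: synth.ConditionPair, width_px: int | None = None):
    """Background-corrected mean intensity of every segment in both groups."""
    values: dict[str, list[float]] = {}
    for name, segments in pair.groups.items():
        vals = []
        for seg in segments:
            wpx = width_px or _band_width_px(seg)
            m = intensity.profile_mean(
                seg.image, seg.trace, wpx, seg.background_roi
            )
            vals.append(m.corrected_mean)
        values[name] = vals
    return values


def quantify_contact(
    segments: list[synth.ContactSegment], config: ContactConfig | None = None
) -> pd.DataFrame:
    """Run the contact estimator on each two-channel segment."""
    rows = []
    for seg in segments:
        cfg = config or ContactConfig()
        res = contact.analyze_segment(seg.er_image, seg.ribo_image, cfg)
        rows.append({
            "fraction_in_mask": res.fraction_in_mask,
            "fraction_in_enlarged": res.fraction_in_enlarged,
            "fraction_flipped": res.fraction_flipped,
            "mask_area_fraction": res.mask_area_fraction,
            "threshold_used": res.threshold_used,
        })
    return pd.DataFrame(rows)


def quantify_branch(
    segments: list[synth.SimulatedSegment],
    window_um: float,
    guard_um: float = 1.0,
    inner_margin_um: float = 0.3,
) -> tuple[list[float], list[float]]:
    """Mean corrected intensity in branch-point windows versus shaft windows.

    Branch windows are centered on each branch point (the inner portion is
    measured, trimming ``inner_margin_um`` per side to limit blur bleed-over);
    shaft windows tile the remaining axon, keeping ``guard_um`` clearance
    from every branch window and from the segment ends.
    """
    branch_vals: list[float] = []
    shaft_vals: list[float] = []
    for seg in segments:
        wpx = _band_width_px(seg)
        total = seg.trace.length_nm
        w_nm = window_um * 1000.0
        g_nm = guard_um * 1000.0
        m_nm = inner_margin_um * 1000.0
        branch_ivals = []
        for b in seg.trace.branch_points_nm:
            lo, hi = b - w_nm / 2.0 + m_nm, b + w_nm / 2.0 - m_nm
            branch_ivals.append((b - w_nm / 2.0, b + w_nm / 2.0))
            m = intensity.profile_mean(
                seg.image, seg.trace, wpx, seg.background_roi,
                s_window_nm=(lo, hi),
            )
            branch_vals.append(m.corrected_mean)
        # shaft: windows of the same width tiling the guarded complement
        edges = [g_nm]
        for lo, hi in branch_ivals:
            edges.extend([lo - g_nm, hi + g_nm])
        edges.append(total - g_nm)
        for lo, hi in zip(edges[::2], edges[1::2]):
            n_win = int((hi - lo) // w_nm)
            for k in range(n_win):
                a = lo + k * w_nm + m_nm
                b2 = lo + (k + 1) * w_nm - m_nm
                m = intensity.profile_mean(
                    seg.image, seg.trace, wpx, seg.background_roi,
                    s_window_nm=(a, b2),
                )
                shaft_vals.append(m.corrected_mean)
    return branch_vals, shaft_vals


def run_experiment(config: dict | str | Path) -> ComparisonReport:
    """Execute one simulate -> quantify -> compare chain deterministically.

    ``config`` keys: ``preset`` (name), ``quantifier`` (``intensity`` or
    ``contact``), ``n`` (segments per group), ``seed``.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    for key in ("preset", "quantifier", "seed"):
        if key not in config:
            raise ConfigError(f"config missing key {key!r}")
    preset = get_preset(config["preset"])
    seed = int(config["seed"])
    quantifier = config["quantifier"]
    n = int(config.get("n", preset.n_replicates))
    h = _config_hash(config)

    if quantifier == "intensity":
        if preset.kind != "condition_pair":
            raise ConfigError(
                f"quantifier 'intensity' needs a condition-pair preset, "
                f"got {preset.kind!r}"
            )
        pair = synth.simulate_condition_pair(preset, n, seed)
        values = quantify_pair(pair)
        ctrl, test = values["control"], values["test"]
        stat = stats.mannwhitneyu(ctrl, test, alternative="two-sided")
        return ComparisonReport(
            preset=preset.name, quantifier=quantifier, seed=seed,
            config_hash=h,
            n={k: len(v) for k, v in values.items()},
            means={k: float(np.mean(v)) for k, v in values.items()},
            sds={k: float(np.std(v, ddof=1)) for k, v in values.items()},
            effect_name="percent_change",
            effect_value=intensity.percent_change(ctrl, test),
            test_name="mannwhitneyu", p_value=float(stat.pvalue),
        )
    if quantifier == "contact":
        if preset.kind != "contact":
            raise ConfigError(
                f"quantifier 'contact' needs a contact preset, got {preset.kind!r}"
            )
        segs = synth.simulate_contact_segments(preset, n, seed)
        df = quantify_contact(
            segs, ContactConfig(dilate_nm=preset.dilate_nm)
        )
        stat = stats.wilcoxon(
            df["fraction_in_mask"], df["fraction_flipped"],
            alternative="greater",
        )
        return ComparisonReport(
            preset=preset.name, quantifier=quantifier, seed=seed,
            config_hash=h,
            n={"segments": len(df)},
            means={c: float(df[c].mean()) for c in df.columns},
            sds={c: float(df[c].std(ddof=1)) for c in df.columns},
            effect_name="mean_fraction_in_mask",
            effect_value=float(df["fraction_in_mask"].mean()),
            test_name="wilcoxon_mask_vs_flipped", p_value=float(stat.pvalue),
            extras={
                "mean_fraction_flipped": float(df["fraction_flipped"].mean())
            },
        )
    raise ConfigError(f"unknown quantifier {quantifier!r}")


def validate_manifest(
    manifest: pd.DataFrame | str | Path,
    allowed_conditions: set[str] | None = None,
    control_condition: str | None = None,
) -> list[str]:
    """Check a measurement manifest; an empty list means valid.

    Flags missing files (any column ending in ``path``), condition labels
    outside the declared set, and batches without control rows.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    issues: list[str] = []
    path_cols = [c for c in manifest.columns if c.endswith("path")]
    for idx, row in manifest.iterrows():
        for c in path_cols:
            if pd.notna(row[c]) and not Path(str(row[c])).exists():
                issues.append(f"row {idx}: missing file {row[c]!r} ({c})")
    if allowed_conditions is not None and "condition" in manifest.columns:
        bad = set(manifest["condition"]) - allowed_conditions
        for label in sorted(bad):
            issues.append(f"unknown condition label {label!r}")
    if control_condition is not None and {"condition", "batch_id"} <= set(
        manifest.columns
    ):
        for batch, grp in manifest.groupby("batch_id"):
            if not (grp["condition"] == control_condition).any():
                issues.append(f"batch {batch!r} has no control rows")
    return issues
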