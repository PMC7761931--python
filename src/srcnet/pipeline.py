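"""End-to-end orchestration: cohort -> preprocessing -> PLV -> features ->
labels -> SFS+LDA classification -> significance threshold -> JSON report.

Every stage is a pure function of its inputs, the configuration and the
seeds, so a fixed configuration reproduces a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import classify, io, panss, preprocess, synthetic, thresholds
from .connectivity import plv_matrix
from .network import assemble_features

log = logging.getLogger("srcnet")


@dataclass
class PairSpec:
    """One binary classification pair.

    ``kind="group"`` contrasts the two cohort groups; ``kind="panss_median"``
    median-splits the subjects of ``group`` (or all subjects if None) on a
    five-factor/subscale score named by ``factor``.
    """

    name: str
    kind: str = "group"
    factor: str | None = None
    group: str | None = None
    positive: str | None = None  # label treated as positive for sensitivity

    def __post_init__(self) -> None:
        if self.kind not in ("group", "panss_median"):
            raise ValueError("kind must be 'group' or 'panss_median'")
        if self.kind == "panss_median" and not self.factor:
            raise ValueError("panss_median pair needs a factor name")


@dataclass
class PipelineConfig:
    """All pipeline parameters; the defaults reproduce the protocol settings
    (2 s epochs, +/-100 uV and theta/alpha > 1 rejection, 30 random epochs,
    SFS capped at 30 features, 10x10-fold CV, alpha = 0.05)."""

    cohort: synthetic.CohortConfig | None = None
    input_dir: str | None = None
    bands: Sequence[str] = ("delta", "theta", "alpha", "alpha1", "alpha2", "beta",
                            "beta1", "beta2", "beta3", "beta4", "gamma")
    amplitude_limit: float = 100.0
    ratio_threshold: float = 1.0
    k_epochs: int = 30
    allow_fewer_epochs: bool = False
    edge_fraction: float = 0.1
    plv_mode: str = "epochs"
    pairs: Sequence[PairSpec] = field(default_factory=lambda: [PairSpec(name="group")])
    mode: str = "paper"
    max_k: int = 30
    inner_cv: int = 10
    n_folds: int = 10
    n_repeats: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of cohort (simulate) or input_dir (load)")


def extract_subject_features(
    epochs: preprocess.EpochSet, config: PipelineConfig, seed
) -> "np.ndarray":
    """Preprocess one subject and return its network feature vector."""
    kept, _ = preprocess.reject_amplitude(epochs, limit=config.amplitude_limit)
    kept, _ = preprocess.reject_theta_alpha(kept, threshold=config.ratio_threshold)
    kept = preprocess.select_epochs(kept, k=config.k_epochs, seed=seed,
                                    allow_fewer=config.allow_fewer_epochs)
    mats = []
    for name in config.bands:
        band = preprocess.get_band(name)
        filtered = preprocess.bandpass(kept, band)
        mats.append(plv_matrix(filtered, edge_fraction=config.edge_fraction,
                               mode=config.plv_mode, band=band))
    return assemble_features(mats)


def _pair_labels(pair: PairSpec, groups: list[str], factor_scores) -> tuple[np.ndarray, np.ndarray]:
    """Row mask and binary labels for one classification pair."""
    groups = np.asarray(groups)
    if pair.kind == "group":
        mask = np.ones(len(groups), dtype=bool)
        labels = groups
    else:
        mask = np.ones(len(groups), dtype=bool) if pair.group is None else groups == pair.group
        scores = [getattr(fs, pair.factor) for fs, m in zip(factor_scores, mask) if m]
        split, _ = panss.median_split(scores)
        labels = np.asarray(split)
    return mask, labels


def run_full(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the whole pipeline and return (optionally write) the report bundle."""
    root = np.random.SeedSequence(config.seed)
    sim_ss, select_ss, classify_ss = root.spawn(3)

    if config.cohort is not None:
        log.info("simulating cohort: %d nodes, %d subjects/group",
                 config.cohort.n_nodes, config.cohort.n_subjects_per_group)
        subjects = synthetic.generate_cohort(config.cohort)
    else:
        log.info("loading cohort from %s", config.input_dir)
        subjects = io.read_cohort(config.input_dir)

    select_seeds = select_ss.spawn(len(subjects))
    vectors = []
    for subj, s_ss in zip(subjects, select_seeds):
        vectors.append(extract_subject_features(
            subj.epochs, config, np.random.default_rng(s_ss)))
    feature_index = vectors[0].index
    x = np.vstack([v.values for v in vectors])
    groups = [s.group for s in subjects]
    factor_scores = [panss.score_factors(s.panss) for s in subjects]

    report: dict = {
        "config": {
            "bands": list(config.bands),
            "amplitude_limit": config.amplitude_limit,
            "ratio_threshold": config.ratio_threshold,
            "k_epochs": config.k_epochs,
            "mode": config.mode,
            "max_k": config.max_k,
            "n_folds": config.n_folds,
            "n_repeats": config.n_repeats,
            "alpha": config.alpha,
            "seed": config.seed,
        },
        "n_subjects": len(subjects),
        "feature_names": [
            f"{b}__{k}" + (f"__{node}" if node is not None else "")
            for b, k, node in feature_index
        ],
        "pairs": {},
    }

    pair_seeds = classify_ss.spawn(len(config.pairs))
    for pair, p_ss in zip(config.pairs, pair_seeds):
        mask, labels = _pair_labels(pair, groups, factor_scores)
        xp = x[mask]
        n = int(mask.sum())
        log.info("pair %s: n=%d, mode=%s", pair.name, n, config.mode)
        cv = classify.run_pair(
            xp, labels, mode=config.mode,
            seed=int(p_ss.generate_state(1)[0] % (2**31 - 1)),
            max_k=config.max_k, inner_cv=config.inner_cv,
            n_folds=config.n_folds, n_repeats=config.n_repeats,
            positive_label=pair.positive,
        )
        spec = thresholds.ThresholdSpec.compute(n=n, c=2, alpha=config.alpha)
        entry = cv.to_dict()
        entry["selected_feature_names"] = [report["feature_names"][i]
                                           for i in cv.selected_features]
        entry["threshold_percent"] = spec.st_alpha
        entry["above_threshold"] = bool(cv.accuracy > spec.st_alpha)
        entry["n"] = n
        report["pairs"][pair.name] = entry

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def summarize_selected(
    report_or_trace,
    feature_names: Sequence[str] | None = None,
    node_regions: dict[str, str] | None = None,
) -> dict:
    """Rank regions and bands by how often they appear among selected features.

    Accepts a full report dict (all pairs pooled) or one pair entry. Node
    region tags come from ``node_regions`` (node label -> region); untagged
    nodes count under "untagged". Equal counts share a rank, mirroring how
    tied entries are reported.
    """
    if isinstance(report_or_trace, dict) and "pairs" in report_or_trace:
        names = []
        for entry in report_or_trace["pairs"].values():
            names.extend(entry["selected_feature_names"])
    elif isinstance(report_or_trace, dict) and "selected_feature_names" in report_or_trace:
        names = list(report_or_trace["selected_feature_names"])
    else:
        names = [feature_names[i] for i in report_or_trace]

    band_counts: dict[str, int] = {}
    region_counts: dict[str, int] = {}
    for name in names:
        parts = name.split("__")
        band_counts[parts[0]] = band_counts.get(parts[0], 0) + 1
        node = parts[2] if len(parts) > 2 else None
        region = (node_regions or {}).get(node, "untagged" if node else "global")
        region_counts[region] = region_counts.get(region, 0) + 1

    def ranked(counts: dict[str, int]) -> list[dict]:
        out = []
        rank = 0
        prev = None
        for i, (key, cnt) in enumerate(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        ):
            if cnt != prev:
                rank = i
                prev = cnt
            out.append({"name": key, "count": cnt, "rank": rank})
        return out

    return {"by_region": ranked(region_counts), "by_band": ranked(band_counts)}
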