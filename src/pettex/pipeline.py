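"""End-to-end orchestration: simulate -> segment -> extract -> agree -> survive.

Stages communicate only through the declared file interfaces (NIfTI
volumes/masks, CSV tables) inside one run directory, so any stage can be
rerun in isolation and the whole run can be reproduced from the manifest.
One master seed fans out to the stages via fixed offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import METRIC_ORDER, agreement_report
from .segmentation import adaptive_threshold_segment, measure_background, t45_segment
from .survival import survival_report
from .synthetic import (
    CohortConfig,
    PerturbationConfig,
    PhantomConfig,
    generate_survival_cohort,
    simulate_paired_cohort,
)
from .texture import FEATURE_NAMES, extract_all
from .volume import PetVolume, load_mask, save_mask

__all__ = ["RunConfig", "run_pipeline", "stage_simulate", "stage_segment_extract",
           "stage_agree", "stage_survive", "paired_feature_tables"]

log = logging.getLogger("pettex")

_SEED_OFFSETS = {"simulate": 0, "cohort": 1}

FEATURE_CSV_COLUMNS = ["lesion_id", "variant", "method", "threshold",
                       "suvmax", "suvmean", "mtv_cm3", "tlg", *FEATURE_NAMES]


@dataclass(frozen=True)
class RunConfig:
    workdir: str = "run"
    n_lesions: int = 10
    methods: tuple[str, ...] = ("adaptive", "t45")
    n_bins: int = 64
    hglze_mode: str = "i2j2"
    prognostic_feature: str = "suv_entropy"
    survival_terms: tuple[str, ...] = ("suv_entropy", "glcm_entropy", "coarseness")
    alpha_agreement: float = 0.05
    alpha_survival: float = round(0.05 / 3, 3)
    plots: bool = False
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be nonempty")
        bad = set(self.methods) - {"adaptive", "t45"}
        if bad:
            raise ValueError(f"unknown segmentation methods: {sorted(bad)}")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("phantom", PhantomConfig),
                         ("perturbation", PerturbationConfig),
                         ("cohort", CohortConfig)):
            if key in d and isinstance(d[key], dict):
                block = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                d[key] = sub(**block)
        for key in ("methods", "survival_terms"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(self, seed=int(seed))


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def paired_feature_tables(
    n_lesions: int,
    seed: int = 0,
    method: str = "adaptive",
    phantom_template: PhantomConfig | None = None,
    perturbation_template: PerturbationConfig | None = None,
    n_bins: int = 64,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a paired lesion cohort and measure every metric in memory.

    Returns ``(hct_table, act_table)`` indexed by lesion id with one column
    per metric (SUVmax/SUVmean/TLG + the 12 texture features), ready for
    :func:`pettex.agreement.agreement_report`. This is the in-memory
    equivalent of the simulate -> segment -> extract stages.
    """
    lesions = simulate_paired_cohort(
        n_lesions, seed=seed, phantom_template=phantom_template,
        perturbation_template=perturbation_template,
    )
    tables = {"hct": [], "act": []}
    for les in lesions:
        for variant in ("hct", "act"):
            vol = les[variant]
            bg = measure_background(vol, les["bg_mask"])
            if method == "adaptive":
                seg = adaptive_threshold_segment(vol, les["seed_mask"], bg)
            else:
                seg = t45_segment(vol, les["seed_mask"])
            feats = extract_all(vol, seg, n_bins=n_bins)
            tables[variant].append({
                "lesion_id": les["lesion_id"], "suvmax": seg.suvmax,
                "suvmean": seg.suvmean, "tlg": seg.tlg, **feats.as_dict(),
            })
    a = pd.DataFrame(tables["hct"]).set_index("lesion_id")[METRIC_ORDER]
    b = pd.DataFrame(tables["act"]).set_index("lesion_id")[METRIC_ORDER]
    return a, b


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, rundir: Path) -> None:
    """Write paired NIfTI volumes and masks plus a lesion index CSV."""
    vols = rundir / "volumes"
    vols.mkdir(parents=True, exist_ok=True)
    lesions = simulate_paired_cohort(
        cfg.n_lesions, seed=cfg.seed + _SEED_OFFSETS["simulate"],
        phantom_template=cfg.phantom, perturbation_template=cfg.perturbation,
    )
    rows = []
    for les in lesions:
        lid = les["lesion_id"]
        les["hct"].save(vols / f"{lid}_hct.nii.gz")
        les["act"].save(vols / f"{lid}_act.nii.gz")
        spacing = les["hct"].spacing
        save_mask(les["seed_mask"], spacing, vols / f"{lid}_seed.nii.gz")
        save_mask(les["bg_mask"], spacing, vols / f"{lid}_bgref.nii.gz")
        rows.append({"lesion_id": lid,
                     "phantom_seed": les["phantom_config"].seed,
                     "perturbation_seed": les["perturbation_config"].seed})
    pd.DataFrame(rows).to_csv(rundir / "lesions.csv", index=False)
    log.info("simulated %d paired lesions", len(lesions))


def stage_segment_extract(cfg: RunConfig, rundir: Path) -> None:
    """Segment each lesion/variant/method and extract the 12 features."""
    vols = rundir / "volumes"
    lesions = pd.read_csv(rundir / "lesions.csv")["lesion_id"]
    rows = []
    for lid in lesions:
        seed_mask = load_mask(vols / f"{lid}_seed.nii.gz")
        bg_mask = load_mask(vols / f"{lid}_bgref.nii.gz")
        for variant in ("hct", "act"):
            vol = PetVolume.load(vols / f"{lid}_{variant}.nii.gz")
            bg = measure_background(vol, bg_mask)
            for method in cfg.methods:
                try:
                    if method == "adaptive":
                        seg = adaptive_threshold_segment(vol, seed_mask, bg)
                    else:
                        seg = t45_segment(vol, seed_mask)
                    feats = extract_all(vol, seg, n_bins=cfg.n_bins,
                                        hglze_mode=cfg.hglze_mode)
                except Exception as err:
                    raise RuntimeError(
                        f"segment/extract failed for lesion {lid} "
                        f"({variant}, {method}): {err}"
                    ) from err
                rows.append({
                    "lesion_id": lid, "variant": variant, "method": method,
                    "threshold": seg.threshold, "suvmax": seg.suvmax,
                    "suvmean": seg.suvmean, "mtv_cm3": seg.mtv_cm3,
                    "tlg": seg.tlg, **feats.as_dict(),
                })
    pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS).to_csv(
        rundir / "features.csv", index=False
    )
    log.info("extracted features for %d lesion-variant-method rows", len(rows))


def _variant_tables(features: pd.DataFrame, method: str):
    sub = features[features["method"] == method]
    metrics = [m for m in METRIC_ORDER if m in sub.columns]
    a = sub[sub["variant"] == "hct"].set_index("lesion_id")[metrics]
    b = sub[sub["variant"] == "act"].set_index("lesion_id")[metrics]
    return a, b


def stage_agree(cfg: RunConfig, rundir: Path) -> None:
    """Per-method agreement report over the paired feature tables."""
    features = pd.read_csv(rundir / "features.csv")
    for method in cfg.methods:
        a, b = _variant_tables(features, method)
        report = agreement_report(a, b)
        report.to_csv(rundir / f"agreement_{method}.csv", index=False)
        if cfg.plots:
            _bland_altman_plots(a, b, rundir / f"ba_plots_{method}")
    log.info("agreement reports written for methods %s", list(cfg.methods))


def _bland_altman_plots(a: pd.DataFrame, b: pd.DataFrame, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .agreement import bland_altman

    outdir.mkdir(parents=True, exist_ok=True)
    for metric in a.columns:
        av, bv = a[metric].to_numpy(), b[metric].to_numpy()
        mean = (av + bv) / 2
        diff = 100 * (bv - av) / mean
        ba = bland_altman(av, bv)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(mean, diff, s=12)
        for y, style in ((ba.mean_pct, "-"), (ba.lrl_pct, "--"), (ba.url_pct, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
        ax.set_xlabel("mean of variants")
        ax.set_ylabel("difference (%)")
        ax.set_title(metric)
        fig.tight_layout()
        fig.savefig(outdir / f"{metric}.png", dpi=100)
        plt.close(fig)


def stage_survive(cfg: RunConfig, rundir: Path) -> None:
    """Generate the linked cohort and run the survival workflow."""
    features = pd.read_csv(rundir / "features.csv")
    a, b = _variant_tables(features, cfg.methods[0])
    cohort_cfg = dataclasses.replace(
        cfg.cohort, n_patients=len(a),
        feature_name=cfg.prognostic_feature,
        seed=cfg.seed + _SEED_OFFSETS["cohort"],
    )
    cohort = generate_survival_cohort(a[cfg.prognostic_feature].to_numpy(),
                                      cohort_cfg)
    cohort.insert(0, "lesion_id", a.index.to_numpy())
    cohort.to_csv(rundir / "cohort.csv", index=False)

    coh = cohort.set_index("patient_id")
    fa = a.set_axis(coh.index)
    fb = b.set_axis(coh.index)
    rep = survival_report(coh, fa, fb, list(cfg.survival_terms),
                          alpha=cfg.alpha_survival)
    rep["roc"].to_csv(rundir / "roc_cutoffs.csv", index=False)
    rep["cox_univariate"].to_csv(rundir / "cox_univariate.csv", index=False)
    rep["cox_adjusted"].to_csv(rundir / "cox_adjusted.csv", index=False)
    rep["concordance"].to_csv(rundir / "concordance.csv", index=False)
    if cfg.plots:
        _km_plots(coh, fa, rep["roc"], rundir / "km_plots")
    log.info("survival reports written (alpha=%.3f)", cfg.alpha_survival)


def _km_plots(cohort: pd.DataFrame, feats: pd.DataFrame,
              roc: pd.DataFrame, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .survival import km_logrank

    outdir.mkdir(parents=True, exist_ok=True)
    for _, row in roc[roc["variant"] == "hct"].iterrows():
        term, cut, direction = row["metric"], row["cutoff"], row["direction"]
        v = feats[term].to_numpy()
        high = v > cut if direction == 1 else v < cut
        if high.all() or (~high).all():
            continue
        curves, p, _ = km_logrank(cohort, np.where(high, "high", "low"))
        fig, ax = plt.subplots(figsize=(4, 3))
        for km in curves.values():
            km.plot_survival_function(ax=ax)
        ax.set_title(f"{term} (log-rank p={p:.3f})")
        ax.set_xlabel("months")
        fig.tight_layout()
        fig.savefig(outdir / f"km_{term}.png", dpi=100)
        plt.close(fig)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_STAGES = [
    ("simulate", stage_simulate),
    ("segment_extract", stage_segment_extract),
    ("agree", stage_agree),
    ("survive", stage_survive),
]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages into ``cfg.workdir`` and write a manifest.

    Any stage failure aborts with the stage name attached; outputs of
    completed stages are retained.
    """
    rundir = Path(cfg.workdir)
    rundir.mkdir(parents=True, exist_ok=True)
    for name, fn in _STAGES:
        try:
            fn(cfg, rundir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "master_seed": cfg.seed,
        "stage_seed_offsets": _SEED_OFFSETS,
        "pettex_version": __version__,
        "numpy_version": np.__version__,
        "outputs": sorted(
            str(p.relative_to(rundir)) for p in rundir.rglob("*") if p.is_file()
        ),
    }
    with open(rundir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return rundir
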