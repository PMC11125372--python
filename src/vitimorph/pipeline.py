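"""Named analysis runs over the imaging -> EFD -> statistics chain.

The study design is a cascade of six analyses that differ only in how
specimen classes map onto analysis groups and in whether a posterior
threshold is applied:

* ``assemblage_pca``   - PCA of the unknown (fossil) specimens only, to
  compare assemblages in shape space;
* ``continental_lda``  - reference classes pooled into two continental
  super-groups, unknowns allocated between them;
* ``eurasian11_lda``   - the Eurasian classes kept separate;
* ``eurasian5_lda``    - the five-class subset closest to the unknowns;
* ``threshold_allocation`` - the five-class posteriors re-allocated under a
  minimum-posterior threshold (default p >= 0.90, below which a specimen is
  "unassigned");
* ``ecotype_lda``      - western vs eastern wild-grapevine ecotypes.

Each run is a data-driven configuration over the same engine; reports echo
the fully resolved configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efd import EllipticFourierFeaturizer
from .imaging import outlines_from_manifest, read_manifest
from .stats import (
    AllocationTable,
    StepwiseLDA,
    classify_unknown,
    loocv_classify,
    round_report,
    run_pca,
    stepwise_select,
    threshold_allocate,
    UNKNOWN_LABEL,
)

__all__ = ["AnalysisConfig", "RunBundle", "run_analysis", "write_reports",
           "ANALYSIS_NAMES"]

ANALYSIS_NAMES = (
    "assemblage_pca",
    "continental_lda",
    "eurasian11_lda",
    "eurasian5_lda",
    "threshold_allocation",
    "ecotype_lda",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Fully explicit configuration of one named analysis."""

    name: str
    manifests: tuple
    group_map: dict = field(default_factory=dict)
    n_points: int = 360
    k_harmonics: int = 6
    p_min: float = 0.90
    f_enter: float = 3.84
    f_remove: float = 2.71
    priors: str = "equal"
    use_pca_scores: bool = True
    pca_variance: float = 0.99
    reselect_per_fold: bool = False
    threshold_policy: str = "otsu"
    rng_seed: int = 0

    def __post_init__(self):
        if self.name not in ANALYSIS_NAMES:
            raise ValueError(
                f"unknown analysis {self.name!r}; expected one of "
                f"{ANALYSIS_NAMES}"
            )
        if not (0.0 < self.p_min <= 1.0):
            raise ValueError("p_min must lie in (0, 1]")
        if self.n_points < 3 or self.k_harmonics < 1:
            raise ValueError("n_points >= 3 and k_harmonics >= 1 required")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["manifests"] = list(self.manifests)
        return d


@dataclass
class RunBundle:
    """Everything one analysis produced, plus the resolved configuration."""

    config: dict
    features: pd.DataFrame          # specimen_id-indexed, group column + a1..d6
    outputs: dict
    log: list


def _log(log: list, step: str, **detail):
    log.append({"step": step, **detail})


def _load_features(cfg: AnalysisConfig, log: list) -> pd.DataFrame:
    manifest = pd.concat(
        [read_manifest(p) for p in cfg.manifests], ignore_index=True
    )
    outlines = outlines_from_manifest(
        manifest, threshold_policy=cfg.threshold_policy, n_points=cfg.n_points
    )
    feat = EllipticFourierFeaturizer(
        k_harmonics=cfg.k_harmonics, n_points=cfg.n_points
    )
    X = feat.fit_transform(outlines)
    df = pd.DataFrame(
        X,
        columns=EllipticFourierFeaturizer.feature_names(cfg.k_harmonics),
        index=manifest["specimen_id"].astype(str),
    )
    df.insert(0, "group", manifest["group"].astype(str).values)
    if "assemblage" in manifest.columns:
        df.insert(1, "assemblage", manifest["assemblage"].astype(str).values)
    _log(log, "features", n_specimens=len(df),
         n_coefficients=X.shape[1])
    return df


def _map_groups(df: pd.DataFrame, group_map: dict) -> pd.DataFrame:
    """Apply the class -> analysis-group mapping; unmapped classes drop out,
    the distinguished "unknown" group always passes through."""
    groups = df["group"]
    mapped = groups.map(lambda g: UNKNOWN_LABEL if g == UNKNOWN_LABEL
                        else group_map.get(g))
    keep = mapped.notna()
    out = df.loc[keep].copy()
    out["group"] = mapped[keep]
    return out


def run_analysis(cfg: AnalysisConfig) -> RunBundle:
    """Execute one named analysis and return its bundle."""
    log: list = []
    _log(log, "config", **cfg.echo())
    df = _load_features(cfg, log)
    feature_cols = [c for c in df.columns if c not in ("group", "assemblage")]
    outputs: dict = {}

    if cfg.name == "assemblage_pca":
        unk = df[df["group"] == UNKNOWN_LABEL]
        if unk.empty:
            raise ValueError("assemblage_pca requires unknown specimens")
        pca = run_pca(unk[feature_cols].to_numpy())
        labels = (unk["assemblage"] if "assemblage" in unk.columns
                  else unk["group"])
        scores = pd.DataFrame(
            pca.scores[:, : min(10, pca.scores.shape[1])],
            index=unk.index,
            columns=[f"PC{i + 1}"
                     for i in range(min(10, pca.scores.shape[1]))],
        )
        scores.insert(0, "assemblage", labels.values)
        outputs["pca_scores"] = scores
        outputs["explained_variance_ratio"] = pca.explained_variance_ratio
        _log(log, "pca",
             pc12_pct=float(100 * pca.explained_variance_ratio[:2].sum()))
        return RunBundle(cfg.echo(), df, outputs, log)

    df = _map_groups(df, cfg.group_map)
    ref = df[df["group"] != UNKNOWN_LABEL]
    unk = df[df["group"] == UNKNOWN_LABEL]
    if ref["group"].nunique() < 2:
        raise ValueError(
            f"{cfg.name}: fewer than 2 reference groups after mapping"
        )
    X_ref = ref[feature_cols].to_numpy()
    y_ref = ref["group"].to_numpy()

    if cfg.use_pca_scores:
        pca = run_pca(X_ref)
        cum = np.cumsum(pca.explained_variance_ratio)
        n_comp = int(np.searchsorted(cum, cfg.pca_variance) + 1)
        n_comp = min(n_comp, pca.scores.shape[1])
        Z_ref = pca.scores[:, :n_comp]
        Z_unk = ((unk[feature_cols].to_numpy() - pca.mean)
                 @ pca.loadings[:, :n_comp]) if len(unk) else np.empty((0, n_comp))
        outputs["pca_n_components"] = n_comp
        outputs["explained_variance_ratio"] = pca.explained_variance_ratio
        _log(log, "pca", n_components=n_comp,
             cumulative_pct=float(100 * cum[n_comp - 1]))
    else:
        Z_ref = X_ref
        Z_unk = unk[feature_cols].to_numpy()

    selected = stepwise_select(Z_ref, y_ref, cfg.f_enter, cfg.f_remove)
    if not selected:
        selected = [j for j in range(Z_ref.shape[1])
                    if not np.isclose(np.var(Z_ref[:, j]), 0.0)]
    _log(log, "stepwise", selected=list(map(int, selected)))

    model = StepwiseLDA(stepwise=False, variables=selected, priors=cfg.priors)
    model.fit(Z_ref, y_ref)
    report = loocv_classify(
        Z_ref, y_ref, variables=selected, priors=cfg.priors,
        reselect_per_fold=cfg.reselect_per_fold,
        f_enter=cfg.f_enter, f_remove=cfg.f_remove,
        ids=list(ref.index),
    )
    outputs["selected_variables"] = selected
    outputs["confusion_pct"] = report.confusion_pct
    outputs["correct_pct"] = report.correct_pct
    outputs["loocv_posteriors"] = report.posteriors
    _log(log, "loocv", correct_pct=report.correct_pct)

    if len(unk):
        posteriors, argmax_table = classify_unknown(
            model, Z_unk, ids=list(unk.index)
        )
        outputs["unknown_posteriors"] = posteriors
        outputs["allocation"] = argmax_table
        if cfg.name == "threshold_allocation":
            outputs["allocation"] = threshold_allocate(posteriors, cfg.p_min)
        _log(log, "allocation",
             threshold=outputs["allocation"].threshold,
             percentages={k: float(v) for k, v in
                          outputs["allocation"].percentages.items()})
    elif cfg.name == "threshold_allocation":
        raise ValueError("threshold_allocation requires unknown specimens")
    return RunBundle(cfg.echo(), df, outputs, log)


# ---------------------------------------------------------------------------
# report writers


def _fmt(x: float) -> str:
    return f"{round_report(x, 1):.1f}"


def _confusion_text(name: str, conf: pd.DataFrame, correct: float) -> str:
    cols = list(conf.columns)
    lines = [f"Analysis: {name}", ""]
    header = ["true_group"] + cols + ["Total"]
    rows = [header]
    for g in conf.index:
        rows.append([str(g)] + [_fmt(v) for v in conf.loc[g]] + ["100.0"])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    for r in rows:
        lines.append("  ".join(s.rjust(w) for s, w in zip(r, widths)))
    lines.append("")
    lines.append(
        f"{_fmt(correct)}% of cross-validated grouped cases correctly "
        "classified."
    )
    return "\n".join(lines) + "\n"


def _allocation_text(name: str, table: AllocationTable) -> str:
    lines = [f"Analysis: {name}",
             f"Unknown specimens: {table.n_unknown}"]
    if table.threshold is not None:
        lines.append(f"Posterior threshold: p >= {table.threshold:g}")
    lines.append("")
    for g, pct in table.percentages.items():
        lines.append(f"{g}: {_fmt(pct)}% (n={int(table.counts[g])})")
    return "\n".join(lines) + "\n"


def write_reports(bundle: RunBundle, outdir) -> list:
    """Write a bundle's CSV and text reports; returns the written paths.

    Tables use one-decimal rounding (half away from zero); identical bundles
    produce byte-identical files.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(path):
        written.append(str(path))
        return path

    with open(save(outdir / "config.json"), "w") as fh:
        json.dump(bundle.config, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(save(outdir / "log.jsonl"), "w") as fh:
        for entry in bundle.log:
            fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
    bundle.features.to_csv(save(outdir / "features.csv"),
                           float_format="%.10g")

    out = bundle.outputs
    name = bundle.config["name"]
    if "pca_scores" in out:
        out["pca_scores"].to_csv(save(outdir / "pca_scores.csv"),
                                 float_format="%.10g")
    if "explained_variance_ratio" in out:
        pd.Series(
            out["explained_variance_ratio"], name="explained_variance_ratio"
        ).rename_axis("component").to_csv(
            save(outdir / "explained_variance.csv"), float_format="%.10g"
        )
    if "confusion_pct" in out:
        conf = out["confusion_pct"]
        rounded = conf.map(lambda v: round_report(v, 1))
        rounded["Total"] = 100.0
        rounded.rename_axis("true_group").to_csv(
            save(outdir / "confusion_matrix.csv"), float_format="%.1f"
        )
        with open(save(outdir / "confusion_matrix.txt"), "w") as fh:
            fh.write(_confusion_text(name, conf, out["correct_pct"]))
    if "loocv_posteriors" in out:
        out["loocv_posteriors"].rename_axis("specimen_id").to_csv(
            save(outdir / "loocv_posteriors.csv"), float_format="%.10g"
        )
    if "unknown_posteriors" in out:
        out["unknown_posteriors"].rename_axis("specimen_id").to_csv(
            save(outdir / "unknown_posteriors.csv"), float_format="%.10g"
        )
    if "allocation" in out:
        table = out["allocation"]
        alloc = pd.DataFrame(
            {
                "percent": round_report(table.percentages.to_numpy(), 1),
                "count": table.counts.to_numpy(),
            },
            index=table.percentages.index,
        )
        alloc.rename_axis("group").to_csv(
            save(outdir / "allocation.csv"), float_format="%.1f"
        )
        with open(save(outdir / "allocation.txt"), "w") as fh:
            fh.write(_allocation_text(name, table))
    return written
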