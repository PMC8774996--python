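"""End-to-end orchestration: segment → Cov–Det features → screening →
boosted classification → metrics, with run manifests.

:class:`SeizureClassifier` bundles the data-dependent stages (two-stage
descriptor screening, per-feature z-scoring, the AdaBoost-of-BP-networks
ensemble) behind a fit/predict surface, so the evaluation protocols can
re-fit everything inside each training fold.  :func:`run_pipeline` drives a
whole run from a :class:`RunConfig` and writes the feature table, the
selection report, the serialized model, the metric tables and a manifest
with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from .boosting import (DEFAULT_DELTA, DEFAULT_L, BoostedEnsemble,
                       BPNetworkConfig, fit_adaboost)
from .exceptions import ConfigError, InvalidArgumentError
from .io import read_bern_dir, read_bonn_dataset
from .metrics import (ProtocolResult, equal_split_eval, loocv_by_subject,
                      ten_fold_cv)
from .selection import (DEFAULT_ALPHA, ProblemSpec, SelectionReport,
                        run_two_stage)
from .synth import LABEL_SEIZURE, SynthConfig, gen_dataset

logger = logging.getLogger("covdet")


# ---------------------------------------------------------------------------
# The fold-refittable classifier
# ---------------------------------------------------------------------------

class SeizureClassifier:
    """Screening + standardisation + boosted ensemble, fit as one unit.

    ``fit`` screens descriptors between the two classes of the training
    table (two-stage nonparametric selection), keeps every sub-segment
    column of each surviving descriptor, z-scores those columns on the
    training data, and trains the AdaBoost ensemble on the standardised
    matrix.  If nothing survives screening, all descriptors are kept
    (flagged) so the classifier remains defined on no-signal data.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, combination: str = "stage2",
                 L: int = DEFAULT_L, delta: float = DEFAULT_DELTA,
                 bp_config: BPNetworkConfig | None = None, seed: int = 0):
        self.alpha = alpha
        self.combination = combination
        self.L = L
        self.delta = delta
        self.bp_config = bp_config or BPNetworkConfig()
        self.seed = seed
        self.report_: SelectionReport | None = None
        self.columns_: list[str] | None = None
        self.ensemble_: BoostedEnsemble | None = None
        self.selection_fallback_: bool = False

    def fit(self, X: pd.DataFrame, y) -> "SeizureClassifier":
        y = np.asarray(y).astype(int)
        if len(X) != y.size:
            raise InvalidArgumentError("X and y length mismatch")
        self.report_ = run_two_stage(X[y == 1], X[y == 0], alpha=self.alpha,
                                     combination=self.combination)
        selected = sorted(self.report_.selected_set())
        self.selection_fallback_ = not selected
        if self.selection_fallback_:
            logger.warning("no descriptor survived screening; keeping all")
            selected = sorted(ft.DESCRIPTOR_NAMES)
        cols = ft.descriptor_columns(X)
        self.columns_ = [c for c in cols
                         if any(c.startswith(d + "_r") for d in selected)]
        Z = X[self.columns_].to_numpy(dtype=float)
        self.mu_ = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Zs = (Z - self.mu_) / self.sd_
        self.ensemble_ = fit_adaboost(Zs, y, L=self.L, cfg=self.bp_config,
                                      delta=self.delta, seed=self.seed)
        return self

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        if self.columns_ is None:
            raise ConfigError("classifier is not fitted")
        return (X[self.columns_].to_numpy(dtype=float) - self.mu_) / self.sd_

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        return self.ensemble_.predict_score(self._transform(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.ensemble_.predict(self._transform(X))

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"format_version": 1,
                "alpha": self.alpha, "combination": self.combination,
                "L": self.L, "delta": self.delta, "seed": self.seed,
                "bp_config": asdict(self.bp_config),
                "columns": self.columns_,
                "mu": self.mu_.tolist(), "sd": self.sd_.tolist(),
                "selection_fallback": self.selection_fallback_,
                "ensemble": self.ensemble_.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "SeizureClassifier":
        bp = d["bp_config"].copy()
        bp["hidden"] = tuple(bp["hidden"])
        obj = cls(alpha=d["alpha"], combination=d["combination"], L=d["L"],
                  delta=d["delta"], bp_config=BPNetworkConfig(**bp),
                  seed=d["seed"])
        obj.columns_ = list(d["columns"])
        obj.mu_ = np.asarray(d["mu"], dtype=float)
        obj.sd_ = np.asarray(d["sd"], dtype=float)
        obj.selection_fallback_ = d.get("selection_fallback", False)
        obj.ensemble_ = BoostedEnsemble.from_dict(d["ensemble"])
        return obj

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SeizureClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Problems
# ---------------------------------------------------------------------------

#: The eight canonical Bonn experiment definitions (positive sets vs. E).
_CANONICAL_PROBLEMS = (
    (("A",), "intersection"),
    (("B",), "intersection"),
    (("C",), "intersection"),
    (("D",), "intersection"),
    (("A", "B"), "intersection"),
    (("C", "D"), "intersection"),
    (("A", "C", "D"), "union"),
    (("A", "B", "C", "D"), "union"),
)


def define_problems(classes, negative_class: str = "E") -> list[ProblemSpec]:
    """Binary problems for the classes present.

    With all five Bonn sets the eight canonical experiments are emitted
    (four singles, two pairwise intersections, two multi-set unions).  For
    other class subsets: one problem per single class, plus the all-classes
    problem (intersection for two classes, union for three or more).
    """
    classes = set(classes)
    if negative_class not in classes:
        raise InvalidArgumentError(f"class {negative_class!r} not present")
    others = tuple(sorted(classes - {negative_class}))
    if not others:
        raise InvalidArgumentError("need at least one class besides the comparator")

    def _spec(pos: tuple[str, ...], comp: str) -> ProblemSpec:
        name = (f"{pos[0]} vs {negative_class}" if len(pos) == 1
                else "{%s} vs %s" % (",".join(pos), negative_class))
        return ProblemSpec(name=name, positive_classes=pos,
                           negative_class=negative_class, composition=comp)

    if others == ("A", "B", "C", "D") and negative_class == "E":
        return [_spec(pos, comp) for pos, comp in _CANONICAL_PROBLEMS]
    problems = [_spec((c,), "intersection") for c in others]
    if len(others) >= 2:
        problems.append(_spec(others, "intersection" if len(others) == 2 else "union"))
    return problems


# ---------------------------------------------------------------------------
# Run configuration and driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    source: str = "synthetic"          # synthetic | bonn | bern
    data_path: str = ""                # dataset root for bonn/bern
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_segments: int = 4
    m_subsegments: int = 32
    overlap: int = 0
    feature_source: str = "cov_rows"
    append_det: bool = False
    mode_binning: str = "fd-value"
    alpha: float = DEFAULT_ALPHA
    combination: str = "stage2"
    L: int = DEFAULT_L
    delta: float = DEFAULT_DELTA
    bp: BPNetworkConfig = field(default_factory=BPNetworkConfig)
    protocol: str = "cv10"             # split | cv10 | loso
    positive_class: str = ""           # default: seizure-like / E
    seed: int = 0
    out_dir: str = "covdet_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        synth = SynthConfig(**raw.pop("synth", {}))
        bp_raw = raw.pop("bp", {})
        if "hidden" in bp_raw:
            bp_raw["hidden"] = tuple(bp_raw["hidden"])
        bp = BPNetworkConfig(**bp_raw)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(synth=synth, bp=bp, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_channels(config: RunConfig):
    if config.source == "synthetic":
        synth = config.synth
        if synth.seed != config.seed:
            synth = SynthConfig(**{**asdict(synth), "seed": config.seed})
        return gen_dataset(synth)
    if not config.data_path or not Path(config.data_path).exists():
        raise ConfigError(f"data path does not exist: {config.data_path!r}")
    if config.source == "bonn":
        root = Path(config.data_path)
        present = tuple(c for c in ("A", "B", "C", "D", "E") if (root / c).is_dir())
        if not present:
            raise ConfigError(f"no Bonn class directories under {root}")
        return read_bonn_dataset(root, classes=present)
    if config.source == "bern":
        return read_bern_dir(config.data_path)
    raise ConfigError(f"unknown source {config.source!r}")


def _positive_class(config: RunConfig, labels: set[str]) -> str:
    if config.positive_class:
        if config.positive_class not in labels:
            raise ConfigError(f"positive class {config.positive_class!r} absent")
        return config.positive_class
    for candidate in (LABEL_SEIZURE, "E", "FC"):
        if candidate in labels:
            return candidate
    raise ConfigError(f"cannot infer positive class from labels {sorted(labels)}")


def _evaluate(config: RunConfig, table: pd.DataFrame, y: np.ndarray,
              factory) -> ProtocolResult:
    if config.protocol == "cv10":
        return ten_fold_cv(table, y, factory, seed=config.seed)
    if config.protocol == "split":
        return equal_split_eval(table, y, factory, seed=config.seed)
    if config.protocol == "loso":
        return loocv_by_subject(table, y, table["subject_id"].to_numpy(), factory)
    raise ConfigError(f"unknown protocol {config.protocol!r}")


def make_classifier_factory(config: RunConfig):
    """A factory of fresh, identically-configured classifiers (per fold)."""
    def factory() -> SeizureClassifier:
        return SeizureClassifier(alpha=config.alpha,
                                 combination=config.combination,
                                 L=config.L, delta=config.delta,
                                 bp_config=config.bp, seed=config.seed)
    return factory


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full method and write all artifacts under ``out_dir``.

    Returns a results dictionary: per-problem pooled metrics, the paths of
    every written file, and the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channels = _load_channels(config)
    table = ft.extract_features(channels, n_segments=config.n_segments,
                                m=config.m_subsegments,
                                feature_source=config.feature_source,
                                append_det=config.append_det,
                                mode_binning=config.mode_binning,
                                overlap=config.overlap)
    feat_path = out / "features.csv"
    ft.write_feature_table(table, feat_path)

    labels = set(table["label"])
    pos = _positive_class(config, labels)
    factory = make_classifier_factory(config)

    if labels == {"A", "B", "C", "D", "E"}:
        problems = define_problems(labels, negative_class="E")
    else:
        neg_classes = tuple(sorted(labels - {pos}))
        problems = [ProblemSpec(name=f"{pos} vs {'+'.join(neg_classes)}",
                                positive_classes=neg_classes,
                                negative_class=pos,
                                composition="union" if len(neg_classes) > 2
                                else "intersection")]

    results: dict = {"problems": {}, "files": [str(feat_path)]}
    metric_rows = []
    for prob in problems:
        if labels == {"A", "B", "C", "D", "E"}:
            mask = table["label"].isin(set(prob.positive_classes) | {"E"})
            sub = table[mask].reset_index(drop=True)
            y = (sub["label"] == "E").astype(int).to_numpy()
        else:
            sub = table.reset_index(drop=True)
            y = (sub["label"] == pos).astype(int).to_numpy()
        res = _evaluate(config, sub, y, factory)
        pooled = res.pooled.as_dict()
        results["problems"][prob.name] = {
            "pooled": pooled, "mean": res.mean(), "std": res.std(),
            "n_test": res.n_test, "n_folds": len(res.panels)}
        metric_rows.append({"problem": prob.name, **pooled})
        logger.info("problem %-22s acc=%.4f (n_test=%d)", prob.name,
                    pooled["acc"], res.n_test)

    metrics_path = out / "metrics.csv"
    pd.DataFrame(metric_rows).to_csv(metrics_path, index=False)
    results["files"].append(str(metrics_path))

    # reference fit on all data (selection report + serialized model)
    first = problems[0]
    if labels == {"A", "B", "C", "D", "E"}:
        mask = table["label"].isin(set(first.positive_classes) | {"E"})
        sub = table[mask].reset_index(drop=True)
        y = (sub["label"] == "E").astype(int).to_numpy()
    else:
        sub = table.reset_index(drop=True)
        y = (sub["label"] == pos).astype(int).to_numpy()
    model = factory().fit(sub, y)
    sel_path = out / "selection_report.csv"
    model.report_.to_csv(sel_path)
    model_path = out / "model.json"
    model.save(model_path)
    results["files"] += [str(sel_path), str(model_path)]

    metrics_json = out / "metrics.json"
    with open(metrics_json, "w") as fh:
        json.dump(results["problems"], fh, indent=1, default=float)
    results["files"].append(str(metrics_json))

    manifest = {"config": config.to_dict(), "seed": config.seed,
                "outputs": {str(Path(f).name): _sha256(Path(f))
                            for f in results["files"]}}
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["files"].append(str(manifest_path))
    results["manifest"] = manifest
    return results
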