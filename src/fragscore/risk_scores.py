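"""The seven published hip-fracture mortality risk scores.

Every weight table, probability transform, and stratum cutoff lives in a
packaged YAML config (``data/default_models.yaml``) rather than in code, so
corrupted source cells can be corrected against the original publications
without touching the scoring engine.  Scores are accumulated as exact
decimals (Holt and HEMA carry two-decimal / half-point weights) so stratum
boundary comparisons never suffer float drift.

Orientation: every score except Sernbo increases with mortality risk; the
Sernbo score increases with expected survival (its config carries
``orientation: -1`` so downstream ROC analysis can orient it).
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

import yaml

from .cohort_io import PatientRecord

__all__ = [
    "MODEL_NAMES",
    "ScoreModelSpec",
    "ScorePanel",
    "ScoringError",
    "ConfigError",
    "load_model_config",
    "attainable_scores",
    "stratify",
    "nhfs_probability",
    "holt_probability",
    "derive_holt_intercept",
    "score_patient",
    "score_all",
    "score_sernbo",
    "score_jiang",
    "score_nhfs",
    "score_holt",
    "score_hema",
    "score_asagecogecc",
    "score_ships",
]

MODEL_NAMES = ("sernbo", "jiang", "nhfs", "holt", "hema", "asagecogecc", "ships")


class ScoringError(ValueError):
    """A variable required by a score is missing or has no defined weight."""

    def __init__(self, model: str, variable: str, message: str):
        self.model = model
        self.variable = variable
        super().__init__(f"{model}: {variable}: {message}")


class ConfigError(ValueError):
    """The model config is structurally invalid (e.g. gapped/overlapping strata)."""


def _dec(x: Any) -> Decimal:
    """Exact decimal from YAML scalar (ints stay ints-valued, floats via str)."""
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


@dataclass(frozen=True)
class Stratum:
    label: str
    lo: Decimal
    hi: Decimal
    lo_inclusive: bool = True
    hi_inclusive: bool = True
    # predicted stratum mortality, percent: point value or (lo, hi) interval
    predicted: Optional[float] = None
    predicted_interval: Optional[tuple[Optional[float], Optional[float]]] = None

    def contains(self, score: Decimal) -> bool:
        lo_ok = score >= self.lo if self.lo_inclusive else score > self.lo
        hi_ok = score <= self.hi if self.hi_inclusive else score < self.hi
        return lo_ok and hi_ok

    def representative_predicted(self, use_upper: bool = True) -> Optional[float]:
        """Point summary of the stratum's predicted mortality (percent)."""
        if self.predicted is not None:
            return self.predicted
        if self.predicted_interval is not None:
            lo, hi = self.predicted_interval
            v = hi if use_upper else lo
            if v is None:  # open bound on the chosen side; fall back
                v = lo if use_upper else hi
            return v
        return None


@dataclass(frozen=True)
class ScoreModelSpec:
    """Declarative definition of one risk model."""

    name: str
    components: tuple[Mapping[str, Any], ...]
    transform: Mapping[str, Any]
    strata: tuple[Stratum, ...]
    orientation: int = 1
    description: str = ""

    @property
    def min_score(self) -> Decimal:
        return min(attainable_scores(self))

    @property
    def max_score(self) -> Decimal:
        return max(attainable_scores(self))


@dataclass(frozen=True)
class ScorePanel:
    """One patient's result under one model."""

    patient_id: str
    model: str
    raw_score: Decimal
    predicted_prob: Optional[float]  # fraction in [0, 1], None if no transform
    stratum: str


# ---------------------------------------------------------------------------
# config loading

def _parse_stratum(model: str, raw: Mapping[str, Any]) -> Stratum:
    pred = raw.get("predicted")
    point = interval = None
    if isinstance(pred, (list, tuple)):
        if len(pred) != 2:
            raise ConfigError(f"{model}: predicted interval must have 2 entries")
        interval = (
            None if pred[0] is None else float(pred[0]),
            None if pred[1] is None else float(pred[1]),
        )
    elif pred is not None:
        point = float(pred)
    return Stratum(
        label=str(raw["label"]),
        lo=_dec(raw["min"]),
        hi=_dec(raw["max"]),
        lo_inclusive=bool(raw.get("min_inclusive", True)),
        hi_inclusive=bool(raw.get("max_inclusive", True)),
        predicted=point,
        predicted_interval=interval,
    )


def load_model_config(path: str | Path | None = None) -> dict[str, ScoreModelSpec]:
    """Load (and validate) a model config; ``None`` loads the packaged default.

    Validation brute-force enumerates each model's attainable score set and
    requires the strata to be pairwise disjoint and to cover every attainable
    score; violations raise :class:`ConfigError`.
    """
    if path is None:
        text = resources.files("fragscore.data").joinpath("default_models.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping) or "models" not in raw:
        raise ConfigError("model config must contain a top-level 'models' mapping")

    specs: dict[str, ScoreModelSpec] = {}
    for name, m in raw["models"].items():
        try:
            spec = ScoreModelSpec(
                name=name,
                components=tuple(m["components"]),
                transform=dict(m.get("transform", {"type": "none"})),
                strata=tuple(_parse_stratum(name, s) for s in m["strata"]),
                orientation=int(m.get("orientation", 1)),
                description=str(m.get("description", "")),
            )
        except KeyError as exc:
            raise ConfigError(f"model {name!r}: missing key {exc}") from exc
        _validate_strata(spec)
        specs[name] = spec
    return specs


def _validate_strata(spec: ScoreModelSpec) -> None:
    scores = attainable_scores(spec)
    for s in scores:
        hits = [st for st in spec.strata if st.contains(s)]
        if len(hits) > 1:
            raise ConfigError(
                f"{spec.name}: strata {[h.label for h in hits]} overlap at score {s}"
            )
        if not hits:
            raise ConfigError(f"{spec.name}: attainable score {s} falls in a stratum gap")


# ---------------------------------------------------------------------------
# scoring engine

def _component_options(comp: Mapping[str, Any]) -> set[Decimal]:
    kind = comp["kind"]
    if kind == "band":
        return {_dec(b["weight"]) for b in comp["bands"]}
    if kind == "map":
        return {_dec(w) for w in comp["map"].values()}
    if kind in ("flag", "threshold"):
        return {Decimal(0), _dec(comp["weight"])}
    raise ConfigError(f"unknown component kind {kind!r}")


def attainable_scores(spec: ScoreModelSpec) -> list[Decimal]:
    """All totals reachable by some covariate combination, by enumeration."""
    option_sets = [sorted(_component_options(c)) for c in spec.components]
    return sorted({sum(combo, Decimal(0)) for combo in itertools.product(*option_sets)})


def _component_weight(
    spec_name: str,
    comp: Mapping[str, Any],
    record: PatientRecord,
    missing_defaults: Mapping[str, Any] | None,
) -> Decimal:
    fname = comp["field"]
    value = getattr(record, fname)
    if value is None and missing_defaults and fname in missing_defaults:
        value = missing_defaults[fname]
    if value is None:
        raise ScoringError(spec_name, fname, "required variable is missing")
    kind = comp["kind"]
    if kind == "band":
        for b in comp["bands"]:
            lo = b.get("min")
            hi = b.get("max")
            if (lo is None or value >= lo) and (hi is None or value <= hi):
                return _dec(b["weight"])
        raise ScoringError(spec_name, fname, f"value {value!r} outside all bands")
    if kind == "map":
        key = value.value if isinstance(value, enum.Enum) else str(value)
        table = comp["map"]
        if key not in table:
            raise ScoringError(spec_name, fname, f"no weight defined for {key!r}")
        return _dec(table[key])
    if kind == "flag":
        return _dec(comp["weight"]) if bool(value) else Decimal(0)
    if kind == "threshold":
        op = comp["op"]
        thr = comp["value"]
        hit = {
            "le": value <= thr,
            "lt": value < thr,
            "ge": value >= thr,
            "gt": value > thr,
        }[op]
        return _dec(comp["weight"]) if hit else Decimal(0)
    raise ConfigError(f"unknown component kind {kind!r}")


def stratify(spec: ScoreModelSpec, score: Decimal) -> str:
    for st in spec.strata:
        if st.contains(score):
            return st.label
    raise ScoringError(spec.name, "score", f"score {score} matches no stratum")


# ---------------------------------------------------------------------------
# probability transforms

def nhfs_probability(score: int | float) -> float:
    """Predicted 30-day mortality (percent) from the NHFS logistic transform.

    ``100 / (1 + exp(5.0122 - 0.481 * score))`` for scores in the attainable
    range 0-10; strictly increasing in the score.
    """
    if not 0 <= score <= 10:
        raise ValueError(f"NHFS score must be in 0..10, got {score}")
    return 100.0 / (1.0 + math.exp(5.0122 - 0.481 * float(score)))


def holt_probability(score: float | Decimal, intercept: float | None) -> float:
    """Predicted mortality (fraction) from the Holt linear predictor.

    The published model is ``1 / (1 + exp(-(constant + sum of coefficients)))``
    but its constant was never printed; it must be supplied explicitly (see
    :func:`derive_holt_intercept`).
    """
    if intercept is None:
        raise ValueError(
            "Holt probability transform is unconfigured: the model's intercept "
            "was not published; supply one (e.g. derive_holt_intercept())"
        )
    return 1.0 / (1.0 + math.exp(-(float(intercept) + float(score))))


def derive_holt_intercept(
    score: float = 2.0, mortality_pct: float = 5.8
) -> float:
    """Back-solve the unpublished Holt intercept from a (score, mortality%) pair.

    The default pair is the published high-risk stratum bound (linear
    predictor 2 -> 5.8% 30-day mortality), giving approximately -4.79; the
    companion bound (4.92 -> 53.2%) is consistent to within rounding.
    """
    p = mortality_pct / 100.0
    if not 0 < p < 1:
        raise ValueError("mortality_pct must be in (0, 100)")
    return math.log(p / (1 - p)) - score


def _predicted_prob(
    spec: ScoreModelSpec, score: Decimal, stratum: str
) -> Optional[float]:
    t = spec.transform.get("type", "none")
    if t == "none":
        return None
    if t == "logistic_percent":
        a, b = float(spec.transform["a"]), float(spec.transform["b"])
        return (100.0 / (1.0 + math.exp(a - b * float(score)))) / 100.0
    if t == "logistic":
        intercept = spec.transform.get("intercept")
        if intercept is None:
            return None  # unconfigured: probability reported as missing
        return holt_probability(score, float(intercept))
    if t == "stratum_table":
        st = next(s for s in spec.strata if s.label == stratum)
        rep = st.representative_predicted()
        return None if rep is None else rep / 100.0
    raise ConfigError(f"unknown transform type {t!r}")


# ---------------------------------------------------------------------------
# public scoring API

def score_patient(
    record: PatientRecord,
    spec: ScoreModelSpec,
    missing_defaults: Mapping[str, Any] | None = None,
) -> ScorePanel:
    """Score one patient under one model; missing variables raise ScoringError."""
    total = sum(
        (_component_weight(spec.name, c, record, missing_defaults) for c in spec.components),
        Decimal(0),
    )
    stratum = stratify(spec, total)
    return ScorePanel(
        patient_id=record.patient_id,
        model=spec.name,
        raw_score=total,
        predicted_prob=_predicted_prob(spec, total, stratum),
        stratum=stratum,
    )


def score_all(
    record: PatientRecord,
    models: Sequence[str] | None = None,
    config: Mapping[str, ScoreModelSpec] | None = None,
    missing_defaults: Mapping[str, Any] | None = None,
) -> tuple[list[ScorePanel], dict[str, str]]:
    """Apply each selected model; per-model failures are reported, not fatal.

    Returns ``(panels, failures)`` where ``failures`` maps model name to the
    failure message for models that could not score this patient.
    """
    config = config or load_model_config()
    names = list(models) if models is not None else list(config)
    panels: list[ScorePanel] = []
    failures: dict[str, str] = {}
    for name in names:
        if name not in config:
            failures[name] = f"unknown model {name!r}"
            continue
        try:
            panels.append(score_patient(record, config[name], missing_defaults))
        except ScoringError as exc:
            failures[name] = str(exc)
    return panels, failures


_DEFAULT_CONFIG: dict[str, ScoreModelSpec] | None = None


def _default_spec(name: str) -> ScoreModelSpec:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = load_model_config()
    return _DEFAULT_CONFIG[name]


def score_sernbo(p: PatientRecord) -> ScorePanel:
    """Sernbo score: age, habitat, walking aids, mental status; 2 or 5 points each."""
    return score_patient(p, _default_spec("sernbo"))


def score_jiang(p: PatientRecord) -> ScorePanel:
    """Jiang et al.: age band, male sex, long-term care, 10 comorbidities."""
    return score_patient(p, _default_spec("jiang"))


def score_nhfs(p: PatientRecord) -> ScorePanel:
    """Nottingham Hip Fracture Score (cognitive-impairment adaptation)."""
    return score_patient(p, _default_spec("nhfs"))


def score_holt(p: PatientRecord) -> ScorePanel:
    """Holt et al. linear predictor (decimal coefficients, exact accumulation)."""
    return score_patient(p, _default_spec("holt"))


def score_hema(p: PatientRecord) -> ScorePanel:
    """HEMA: nine variables, half-point resolution, maximum 12."""
    return score_patient(p, _default_spec("hema"))


def score_asagecogecc(p: PatientRecord) -> ScorePanel:
    """ASAgeCoGeCC: age, CCI, cognition, ASA, sex."""
    return score_patient(p, _default_spec("asagecogecc"))


def score_ships(p: PatientRecord) -> ScorePanel:
    """SHiPS: sex, age, fracture site, nursing certification, comorbidities."""
    return score_patient(p, _default_spec("ships"))
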