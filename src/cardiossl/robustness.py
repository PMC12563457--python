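"""Adversarial attacks, attack-effect categorization, and OOD scoring.

FGSM takes a single step of size epsilon along the sign of the input
gradient of the BCE loss; PGD iterates smaller signed steps with projection
back onto the L-infinity ball (and onto [0, 1]).  Attack impact is reported
as the clean-minus-adversarial accuracy drop and bucketed into the three
verbal categories used by the study: ``no_effect`` (< 1 percentage point),
``less_effect`` (1-10 pp) and ``effect`` (> 10 pp).

The OOD score is the mean overconfidence beyond the 0.5 decision threshold
on out-of-distribution inputs: ``mean(max(conf - 0.5, 0))`` with
``conf = max(p, 1 - p)``.  It lives in [0, 0.5]; 0 means the model is
maximally uncertain on foreign inputs (the desired behaviour), 0.5 means it
is always fully confident about them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttackParams",
    "RobustnessReport",
    "LogisticModel",
    "fgsm",
    "pgd",
    "attack_effect",
    "ood_score",
    "categorize_drop",
]


@dataclass(frozen=True)
class AttackParams:
    """L-infinity attack configuration (intensity units)."""

    epsilon: float = 0.03
    step_size: float | None = None  # defaults to epsilon / 4
    n_steps: int = 10
    random_start: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        alpha = self.alpha
        if self.epsilon > 0 and self.n_steps > 1 and not 0 < alpha <= self.epsilon:
            raise ValueError("step_size must satisfy 0 < alpha <= epsilon")

    @property
    def alpha(self) -> float:
        return self.epsilon / 4.0 if self.step_size is None else self.step_size


@dataclass
class RobustnessReport:
    clean_accuracy: float
    adv_accuracy: dict[str, float] = field(default_factory=dict)
    accuracy_drop: dict[str, float] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)
    ood_score: float | None = None

    def to_dict(self) -> dict:
        return {"clean_accuracy": self.clean_accuracy,
                "adv_accuracy": dict(self.adv_accuracy),
                "accuracy_drop": dict(self.accuracy_drop),
                "category": dict(self.category),
                "ood_score": self.ood_score}


class LogisticModel:
    """Toy differentiable classifier p = sigmoid(w.x + b) on flat inputs.

    Exposes the same ``predict`` / ``input_gradient`` surface as the CNN
    models, so it serves as a closed-form oracle for the attack contracts.
    """

    def __init__(self, w, b: float = 0.0):
        self.w = np.asarray(w, dtype=np.float64)
        self.b = float(b)

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = np.asarray(x, dtype=np.float64).reshape(len(x), -1) @ self.w + self.b
        return 1.0 / (1.0 + np.exp(-z))

    def input_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        p = self.predict(x)
        delta = (p - np.asarray(y, dtype=np.float64)) / len(x)
        return (delta[:, None] * self.w).reshape(x.shape)


def _gradient(model, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    g = model.input_gradient(x, y)
    if not np.isfinite(g).all():
        raise FloatingPointError("non-finite attack gradient")
    return g


def fgsm(model, x: np.ndarray, y: np.ndarray, epsilon: float) -> np.ndarray:
    """Single gradient-sign step of size epsilon, clipped to [0, 1]."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    if epsilon == 0:
        return x.copy()
    g = _gradient(model, x, np.asarray(y))
    return np.clip(x + epsilon * np.sign(g, dtype=np.float64), 0.0, 1.0)


def pgd(model, x: np.ndarray, y: np.ndarray,
        params: AttackParams) -> np.ndarray:
    """Iterated signed steps projected onto the epsilon-ball and [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    eps = params.epsilon
    if eps == 0:
        return x.copy()
    y = np.asarray(y)
    adv = x.copy()
    if params.random_start:
        rng = np.random.default_rng(params.seed)
        adv = np.clip(x + rng.uniform(-eps, eps, x.shape), 0.0, 1.0)
    for _ in range(params.n_steps):
        g = _gradient(model, adv, y)
        adv = adv + params.alpha * np.sign(g, dtype=np.float64)
        adv = np.clip(np.clip(adv, x - eps, x + eps), 0.0, 1.0)
    return adv


def categorize_drop(drop: float, minor: float = 0.01,
                    major: float = 0.10) -> str:
    if drop < minor:
        return "no_effect"
    if drop <= major:
        return "less_effect"
    return "effect"


def attack_effect(model, x: np.ndarray, y: np.ndarray,
                  params: AttackParams,
                  attacks: tuple[str, ...] = ("fgsm", "pgd")
                  ) -> RobustnessReport:
    """Clean vs. adversarial accuracy (threshold 0.5) per attack."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("attack evaluation needs a non-empty set")
    y = np.asarray(y)
    clean = float(np.mean((model.predict(x) >= 0.5) == y))
    report = RobustnessReport(clean_accuracy=clean)
    for name in attacks:
        if name == "fgsm":
            adv = fgsm(model, x, y, params.epsilon)
        elif name == "pgd":
            adv = pgd(model, x, y, params)
        else:
            raise ValueError(f"unknown attack {name!r}")
        acc = float(np.mean((model.predict(adv) >= 0.5) == y))
        drop = clean - acc
        report.adv_accuracy[name] = acc
        report.accuracy_drop[name] = drop
        report.category[name] = categorize_drop(drop)
    return report


def ood_score(model, ood_images: np.ndarray) -> float:
    """Mean overconfidence beyond the 50 percent threshold on foreign inputs."""
    ood_images = np.asarray(ood_images)
    if len(ood_images) == 0:
        raise ValueError("OOD scoring needs a non-empty set")
    p = np.asarray(model.predict(ood_images), dtype=np.float64)
    conf = np.maximum(p, 1.0 - p)
    return float(np.mean(np.maximum(conf - 0.5, 0.0)))
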