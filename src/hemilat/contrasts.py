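"""Contrast construction for the pairwise laterality-index comparison system.

Three domains are compared pairwise: faces, objects, and a text composite
whose beta is the equal-weight mean of the words, inverted-words, and
letter-strings conditions.  Each domain's selectivity contrast can use one
of three baselines:

* ``full``     - the domain vs. the balanced mean of the other two domains
                 (e.g. faces: F - (T + O) / 2, with the text domain's 1/2
                 share spread as 1/6 per text condition);
* ``heldout``  - the domain vs. a single held-out third domain;
* ``fixation`` - the domain's betas against the implicit rest baseline
                 (positive weights only).

Weights are laid over (condition, run) beta columns and summed over the
runs of the requested split (odd runs {1, 3, 5} vs. even runs {2, 4}), so
the two sides of a pairwise comparison come from disjoint run sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import TEXT_CONDITIONS

__all__ = [
    "BASELINES",
    "DOMAINS",
    "SPLITS",
    "ContrastVector",
    "domain_conditions",
    "split_runs",
    "build_domain_contrast",
]

BASELINES = ("full", "heldout", "fixation")
DOMAINS = ("faces", "objects", "text")
SPLITS = {"odd": (1, 3, 5), "even": (2, 4), "all": (1, 2, 3, 4, 5)}


def domain_conditions(domain: str, text_conditions=TEXT_CONDITIONS) -> tuple[str, ...]:
    """Stimulus conditions composing a domain; text is the three-way composite."""
    if domain == "text":
        return tuple(text_conditions)
    if domain in ("faces", "objects"):
        return (domain,)
    raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")


def split_runs(run_split: str, n_runs: int = 5) -> tuple[int, ...]:
    if run_split not in SPLITS:
        raise ValueError(f"unknown run split {run_split!r}")
    return tuple(r for r in SPLITS[run_split] if r <= n_runs)


@dataclass
class ContrastVector:
    """Named weights over (condition, run) beta columns."""

    weights: dict[tuple[str, int], float]
    category: str = ""
    baseline: str = ""
    run_split: str = ""
    heldout: str | None = None

    def weight_sum(self) -> float:
        return float(sum(self.weights.values()))

    def per_run_weights(self, run: int) -> dict[str, float]:
        return {c: w for (c, r), w in self.weights.items() if r == run}

    def validate(self) -> None:
        if self.baseline in ("full", "heldout"):
            if abs(self.weight_sum()) > 1e-12:
                raise ValueError(
                    f"{self.baseline} contrast weights sum to {self.weight_sum()}, "
                    "expected 0"
                )
        elif self.baseline == "fixation":
            if any(w < 0 for w in self.weights.values()):
                raise ValueError("fixation contrast must have nonnegative weights")


def _domain_weights(domain: str, total: float,
                    text_conditions=TEXT_CONDITIONS) -> dict[str, float]:
    """Spread ``total`` weight equally over a domain's conditions, so every
    sampled domain carries equal total weight."""
    conds = domain_conditions(domain, text_conditions)
    return {c: total / len(conds) for c in conds}


def build_domain_contrast(
    category: str,
    baseline: str,
    run_split: str = "all",
    heldout_category: str | None = None,
    n_runs: int = 5,
    text_conditions=TEXT_CONDITIONS,
) -> ContrastVector:
    """Contrast for one domain under one baseline, summed over a run split.

    For the faces / full example on the odd split, each odd run carries
    faces +1, objects -1/2, and each text condition -1/6.
    """
    if baseline not in BASELINES:
        raise ValueError(f"unknown baseline {baseline!r}; expected one of {BASELINES}")
    if category not in DOMAINS:
        raise ValueError(f"unknown category {category!r}; expected one of {DOMAINS}")
    if baseline == "heldout":
        if heldout_category is None:
            raise ValueError("heldout baseline requires heldout_category")
        if heldout_category == category:
            raise ValueError("held-out category must differ from the target category")
        if heldout_category not in DOMAINS:
            raise ValueError(f"unknown held-out category {heldout_category!r}")
    elif heldout_category is not None:
        raise ValueError(f"heldout_category is only valid with the heldout baseline")

    per_run: dict[str, float] = dict(_domain_weights(category, 1.0, text_conditions))
    if baseline == "full":
        others = [d for d in DOMAINS if d != category]
        for d in others:
            for c, w in _domain_weights(d, -0.5, text_conditions).items():
                per_run[c] = per_run.get(c, 0.0) + w
    elif baseline == "heldout":
        for c, w in _domain_weights(heldout_category, -1.0, text_conditions).items():
            per_run[c] = per_run.get(c, 0.0) + w

    runs = split_runs(run_split, n_runs)
    weights = {(c, r): w for r in runs for c, w in per_run.items() if w != 0.0}
    cv = ContrastVector(
        weights=weights, category=category, baseline=baseline,
        run_split=run_split, heldout=heldout_category,
    )
    cv.validate()
    return cv
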