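"""Backward covariate selection on the occurrence submodel.

The full model is simplified one term at a time using the effect size and
uncertainty of the fitted species relationships.  A term is *retained* when
its community hypermean 95% HDI excludes zero or any individual species
coefficient's 95% HDI excludes zero; among the non-retained terms the one
with the smallest |hypermean posterior median| / HDI-width ratio is dropped,
interactions and ecoregion offsets before the main effects they involve, and
the reduced model is refit.  Selection stops when every remaining term is
retained.  Detection covariates are left out of selection by default; the
``select_detection`` flag is reserved for joint selection.

A non-convergent intermediate fit (any hypermean split R-hat above the
threshold) is retried once with doubled chains length, after which selection
aborts and returns the partial trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ModelSpec
from .field_data import Dataset
from .inference import PosteriorSamples, hdi, run_mcmc, split_rhat

__all__ = ["TermMetrics", "SelectionStep", "SelectionTrace", "backward_select"]

_PROTECTED = {"intercept", "ecoregion", "year"}


@dataclass
class TermMetrics:
    term: str
    hypermean_median: float
    hypermean_hdi: tuple
    species_hdis: dict
    retained: bool
    score: float            # |median| / HDI width; small = weak and uncertain

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "hypermean_median": self.hypermean_median,
            "hypermean_hdi": list(self.hypermean_hdi),
            "species_hdis": {k: list(v) for k, v in self.species_hdis.items()},
            "retained": self.retained,
            "score": self.score,
        }


@dataclass
class SelectionStep:
    dropped: str
    metrics: list            # TermMetrics for every candidate at this step


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)
    final_spec: ModelSpec | None = None
    aborted: bool = False

    def to_dict(self) -> dict:
        return {
            "steps": [{"dropped": s.dropped,
                       "metrics": [m.to_dict() for m in s.metrics]}
                      for s in self.steps],
            "final_spec": None if self.final_spec is None
            else self.final_spec.to_json(),
            "aborted": self.aborted,
        }


def _term_metrics(ps: PosteriorSamples, spec: ModelSpec) -> list:
    design = ps.design
    out = []
    for term in spec.occ_terms():
        if term in _PROTECTED:
            continue
        col = term
        mu = ps.pooled(f"mu_beta[{col}]")
        mu_hdi = hdi(mu, 0.95)
        excludes = mu_hdi[0] > 0 or mu_hdi[1] < 0
        sp_hdis = {}
        for sp in design.species:
            lo, hi = hdi(ps.pooled(f"beta[{sp},{col}]"), 0.95)
            sp_hdis[sp] = (lo, hi)
            excludes = excludes or lo > 0 or hi < 0
        width = mu_hdi[1] - mu_hdi[0]
        med = float(np.median(mu))
        out.append(TermMetrics(
            term=term, hypermean_median=med, hypermean_hdi=mu_hdi,
            species_hdis=sp_hdis, retained=bool(excludes),
            score=abs(med) / width if width > 0 else np.inf,
        ))
    return out


def _fit_converged(ps: PosteriorSamples, spec: ModelSpec, threshold: float) -> bool:
    for term in ["intercept"] + spec.occ_terms():
        name = f"mu_beta[{term}]"
        if name in ps.names and split_rhat(ps.get(name)) > threshold:
            return False
    return True


def backward_select(full_spec: ModelSpec, data: Dataset,
                    fit_settings: dict | None = None, seed: int = 0,
                    rhat_threshold: float = 1.2) -> SelectionTrace:
    """Iteratively drop the weakest occurrence term until all are retained.

    ``fit_settings`` forwards to :func:`run_mcmc` (chains, iterations,
    warmup...).  The final spec is always a sub-spec of the input and never
    violates the hierarchy: an interaction or ecoregion offset is removed
    before the main effect it depends on.
    """
    fit_settings = dict(fit_settings or {})
    fit_settings.setdefault("n_chains", 2)
    fit_settings.setdefault("n_iter", 1200)
    fit_settings.setdefault("n_warmup", 600)
    fit_settings.setdefault("check_convergence", False)

    trace = SelectionTrace()
    spec = full_spec
    seeds = np.random.SeedSequence(seed).generate_state(200) % (2 ** 31)
    step = 0
    while True:
        ps = run_mcmc(spec, data, seed=int(seeds[step]), **fit_settings)
        if not _fit_converged(ps, spec, rhat_threshold):
            longer = dict(fit_settings)
            longer["n_iter"] = 2 * fit_settings["n_iter"]
            longer["n_warmup"] = 2 * fit_settings["n_warmup"]
            ps = run_mcmc(spec, data, seed=int(seeds[step + 100]), **longer)
            if not _fit_converged(ps, spec, rhat_threshold):
                trace.aborted = True
                trace.final_spec = spec
                return trace
        metrics = _term_metrics(ps, spec)
        droppable = [m for m in metrics
                     if not m.retained and spec.is_droppable(m.term)]
        if not droppable:
            trace.final_spec = spec
            return trace
        weakest = min(droppable, key=lambda m: (m.score, m.term))
        trace.steps.append(SelectionStep(dropped=weakest.term, metrics=metrics))
        spec = spec.drop_term(weakest.term)
        step += 1
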