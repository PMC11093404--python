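"""Production and comprehension harnesses plus effect statistics.

``run_production`` feeds each preamble to each model instance, links the
next-word distribution to a singular/plural completion probability, and
derives the *error rate*: the linked probability of the verb form
incongruent with the subject's grammatical number (a continuous quantity —
exactly what a beta regression on error probabilities consumes).  Paradigms
without a canonical agreement pattern (disjunctions, notional number) are
summarized by the plural-agreement rate instead.

``run_comprehension`` records per-token surprisal and takes the value at
the critical token as the simulated reading-time measure.

Effects follow the convention: attraction = mean(mismatch) − mean(match),
aggregated within item cells, then across items, separately per model
instance; instance-level values feed the mixed-effects analyses as grouped
observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import linking
from .linking import UndefinedCompletionError
from .neural_lm import LanguageModel, next_word_distribution_batch, batch_token_log2probs
from .stimuli import ExperimentItem

__all__ = [
    "TrialResult",
    "EffectSummary",
    "run_production",
    "run_comprehension",
    "attraction_effect",
    "asymmetry_contrasts",
    "make_oracle_predictor",
    "OraclePredictor",
]

logger = logging.getLogger(__name__)

#: canonical column order of a tidy trial table
TrialResult = pd.DataFrame


@dataclass
class EffectSummary:
    """A named per-instance effect (optionally split by grouping levels)."""

    name: str
    response: str
    table: pd.DataFrame  # columns: instance [, grouping...], value

    def mean(self) -> float:
        return float(self.table["value"].mean())


def _condition_columns(items) -> list[str]:
    cols: list[str] = []
    for it in items:
        for f in it.condition:
            if f not in cols:
                cols.append(f)
    return cols


def _base_row(instance, it: ExperimentItem, cond_cols):
    row = {"instance": instance, "paradigm": it.paradigm, "item": it.item}
    for c in cond_cols:
        row[c] = it.condition.get(c)
    return row


def run_production(models, items, rule: str = "one_sample", n: int | None = None,
                   ) -> TrialResult:
    """One row per instance x item x condition cell.

    ``models`` may be trained :class:`LanguageModel` instances or oracle
    predictors (objects with ``completion_p_singular(item, instance)``).
    Items whose candidate pair fails (out of vocabulary, zero mass) are
    collected in ``df.attrs["errors"]`` and the run continues.
    """
    items = [it for it in items if it.measure == "completion"]
    cond_cols = _condition_columns(items)
    rows, errors = [], []
    for k, model in enumerate(models):
        if hasattr(model, "completion_p_singular"):
            p_sgs = [model.completion_p_singular(it, k) for it in items]
            ties = [False] * len(items)
        else:
            dists = next_word_distribution_batch(model, [list(it.tokens) for it in items])
            p_sgs, ties = [], []
            for it, dist in zip(items, dists):
                try:
                    if rule == "one_sample":
                        cp = linking.one_sample(dist, it.candidate, model.vocab, item_id=it.item)
                    elif rule == "max_prob":
                        cp = linking.max_prob(dist, it.candidate, model.vocab, item_id=it.item)
                    elif rule == "n_sample":
                        cp = linking.n_sample(dist, it.candidate, model.vocab, n, item_id=it.item)
                    else:
                        raise ValueError(f"unknown linking rule {rule!r}")
                except (UndefinedCompletionError, ValueError) as e:
                    errors.append((it.paradigm, it.item, dict(it.condition), str(e)))
                    p_sgs.append(np.nan)
                    ties.append(False)
                    continue
                p_sgs.append(cp.p_singular)
                ties.append(cp.tie)
        for it, p_sg, tie in zip(items, p_sgs, ties):
            row = _base_row(k, it, cond_cols)
            row["p_singular"] = p_sg
            row["plural_rate"] = 1.0 - p_sg if p_sg == p_sg else np.nan
            subj = it.condition.get("subject_number")
            if subj == "sg":
                row["error_rate"] = 1.0 - p_sg
            elif subj == "pl":
                row["error_rate"] = p_sg
            else:
                row["error_rate"] = np.nan  # no canonical agreement pattern
            row["tie"] = tie
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["errors"] = errors
    df.attrs["rule"] = rule
    if errors:
        logger.warning("%d production items failed linking", len(errors))
    return df


def run_comprehension(models, items) -> TrialResult:
    """Per-token surprisals; the measure is surprisal at the critical token."""
    items = [it for it in items if it.measure == "reading"]
    cond_cols = _condition_columns(items)
    for it in items:
        if it.critical_index is None or it.critical_index >= len(it.tokens):
            raise ValueError(f"item {it.item}: critical index beyond sentence length")
    rows = []
    for k, model in enumerate(models):
        if isinstance(model, LanguageModel):
            series = [-lp for lp in batch_token_log2probs(model, [list(it.tokens) for it in items])]
        else:
            series = [linking.surprisal_series(model, it.tokens) for it in items]
        for it, s in zip(items, series):
            row = _base_row(k, it, cond_cols)
            row["surprisal"] = float(s[it.critical_index])
            row["critical_index"] = it.critical_index
            row["surprisals"] = tuple(np.round(s, 6))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effect statistics
# ---------------------------------------------------------------------------

def _cell_means(results: pd.DataFrame, response: str, by: list[str]) -> pd.DataFrame:
    # average within item cells first, then across items
    keep = results.dropna(subset=[response])
    if "tie" in keep.columns:
        n_tie = int(keep["tie"].sum())
        if n_tie:
            logger.warning("excluding %d tied max-prob trials from effect summary", n_tie)
        keep = keep[~keep["tie"].astype(bool)]
    per_item = keep.groupby(["instance", "item", *by], observed=True)[response].mean()
    return per_item.groupby(["instance", *by], observed=True).mean().reset_index()


def _default_response(results: pd.DataFrame) -> str:
    return "surprisal" if "surprisal" in results.columns else "error_rate"


def attraction_effect(results: pd.DataFrame, factor: str = "attractor_match",
                      grouping: tuple[str, ...] = (), response: str | None = None,
                      ) -> EffectSummary:
    """mismatch mean − match mean, per instance (and per grouping level)."""
    response = response or _default_response(results)
    by = [factor, *grouping]
    means = _cell_means(results, response, by)
    wide = means.pivot_table(index=["instance", *grouping], columns=factor,
                             values=response, observed=True)
    for level in ("match", "mismatch"):
        if level not in wide.columns:
            raise ValueError(f"missing cell: {factor}={level}")
    out = (wide["mismatch"] - wide["match"]).rename("value").reset_index()
    return EffectSummary(name="attraction", response=response, table=out)


def _difference_of(table: pd.DataFrame, column: str, hi: str, lo: str,
                   name: str, response: str) -> EffectSummary:
    wide = table.pivot_table(index="instance", columns=column, values="value",
                             observed=True)
    out = (wide[hi] - wide[lo]).rename("value").reset_index()
    return EffectSummary(name=name, response=response, table=out)


def asymmetry_contrasts(results: pd.DataFrame) -> dict[str, EffectSummary]:
    """Paradigm-appropriate second-order contrasts, per instance.

    * ``number_asymmetry`` (completion with a subject_number factor):
      attraction with singular subjects − attraction with plural subjects.
    * ``grammaticality_asymmetry`` (reading): attraction in ungrammatical −
      attraction in grammatical sentences.  For surprisal, attraction in
      ungrammatical sentences is facilitatory (negative), so a human-like
      asymmetry yields a negative value.
    * ``distance_contrast`` (double-PP): attraction from the syntactically
      closer attractor − from the linearly closer one, each marginalizing
      over the other attractor's condition.
    * ``plural_rate_contrast``: plural-agreement rate difference across the
      paradigm's named factor (disjunct order, preposition bias).
    """
    paradigm = results["paradigm"].iloc[0]
    out: dict[str, EffectSummary] = {}
    if paradigm == "bock_cutting":
        attr = attraction_effect(results, grouping=("subject_number",))
        out["attraction"] = attraction_effect(results)
        out["number_asymmetry"] = _difference_of(
            attr.table, "subject_number", "sg", "pl", "number_asymmetry", attr.response)
        out["modifier_contrast"] = _difference_of(
            attraction_effect(results, grouping=("modifier",)).table,
            "modifier", "pp", "rc", "modifier_contrast", attr.response)
    elif paradigm == "franck":
        syn = attraction_effect(results, factor="syntactic_match")
        lin = attraction_effect(results, factor="linear_match")
        out["attraction_syntactic"] = syn
        out["attraction_linear"] = lin
        merged = syn.table.merge(lin.table, on="instance", suffixes=("_syn", "_lin"))
        merged["value"] = merged["value_syn"] - merged["value_lin"]
        out["distance_contrast"] = EffectSummary(
            "distance_contrast", syn.response, merged[["instance", "value"]])
    elif paradigm == "haskell":
        means = _cell_means(results, "plural_rate", ["closer_number"])
        means = means.rename(columns={"plural_rate": "value"})
        out["plural_rate_contrast"] = _difference_of(
            means, "closer_number", "pl", "sg", "plural_rate_contrast", "plural_rate")
    elif paradigm == "humphreys":
        means = _cell_means(results, "plural_rate", ["preposition_bias"])
        means = means.rename(columns={"plural_rate": "value"})
        out["plural_rate_contrast"] = _difference_of(
            means, "preposition_bias", "distributive", "collective",
            "plural_rate_contrast", "plural_rate")
    elif paradigm in ("parker_an", "wagers"):
        attr = attraction_effect(results, grouping=("grammaticality",))
        out["attraction"] = attraction_effect(results)
        out["grammaticality_asymmetry"] = _difference_of(
            attr.table, "grammaticality", "ungram", "gram",
            "grammaticality_asymmetry", attr.response)
        if paradigm == "parker_an":
            arg = attraction_effect(results, grouping=("argument",))
            out["argument_contrast"] = _difference_of(
                arg.table, "argument", "oblique", "core",
                "argument_contrast", arg.response)
    else:
        raise ValueError(f"no contrasts registered for paradigm {paradigm!r}")
    return out


# ---------------------------------------------------------------------------
# oracle predictor (test double for harness + stats validation)
# ---------------------------------------------------------------------------

class OraclePredictor:
    """Mock production model with known injected effects.

    The linear predictor (log-odds) is built from ``effects``: a mapping
    from conjunctions of (factor, level) pairs to log-odds contributions,
    e.g. ``{(("attractor_match", "mismatch"),): 1.0}``.  For paradigms with
    a subject_number factor the predictor models the *error* probability
    (the subject-incongruent form) and converts it to ``p_singular``; for
    paradigms without one it models the plural-agreement probability.
    Item and instance intercepts are Gaussian; optional beta noise with
    precision ``phi`` keeps the trial expectation equal to the logistic
    mean.  Every random draw is keyed by (seed, item, instance, condition),
    so results for one instance are invariant to batch composition.
    """

    def __init__(self, effects: dict, intercept: float = 0.0,
                 item_sd: float = 0.0, instance_sd: float = 0.0,
                 phi: float | None = None, seed: int = 0):
        self.effects = dict(effects)
        self.intercept = intercept
        self.item_sd = item_sd
        self.instance_sd = instance_sd
        self.phi = phi
        self.seed = int(seed)

    def _intercept_draw(self, kind: int, index: int, sd: float) -> float:
        if sd == 0.0:
            return 0.0
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(kind, index)))
        return float(rng.normal(0.0, sd))

    def linear_predictor(self, item: ExperimentItem, instance: int) -> float:
        eta = self.intercept
        for conj, beta in self.effects.items():
            terms = conj if isinstance(conj[0], tuple) else (conj,)
            ok = True
            for factor, level in terms:
                if factor not in item.condition:
                    raise ValueError(f"unknown factor {factor!r} for paradigm {item.paradigm}")
                if item.condition[factor] != level:
                    ok = False
            if ok:
                eta += beta
        eta += self._intercept_draw(1, item.item, self.item_sd)
        eta += self._intercept_draw(2, instance, self.instance_sd)
        return eta

    def completion_p_singular(self, item: ExperimentItem, instance: int) -> float:
        mu = 1.0 / (1.0 + np.exp(-self.linear_predictor(item, instance)))
        if self.phi is not None:
            import zlib
            desc = repr((item.item, instance, tuple(sorted(item.condition.items()))))
            key = zlib.crc32(desc.encode())  # stable across processes
            rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(3, key)))
            mu = float(rng.beta(mu * self.phi, (1.0 - mu) * self.phi))
            mu = min(max(mu, 1e-9), 1.0 - 1e-9)
        subj = item.condition.get("subject_number")
        if subj == "sg":
            return 1.0 - mu   # mu is the error (plural-form) probability
        if subj == "pl":
            return mu         # mu is the error (singular-form) probability
        return 1.0 - mu       # mu is the plural-agreement probability


def make_oracle_predictor(effects: dict, **kwargs) -> OraclePredictor:
    """Factory for :class:`OraclePredictor`; see its docstring."""
    return OraclePredictor(effects, **kwargs)
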