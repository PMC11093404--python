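"""Orchestration: run configuration, the toy end-to-end driver, and the CLI.

``replicate_toy`` wires the whole pipeline together at a configurable
scale: generate a corpus, train word-prediction-only and multitask model
instance sets, generate paradigm items, run the production/reading
simulations, fit the mixed-effects analyses, run the probing analyses, and
write per-paradigm effect tables plus a run manifest.  Every random draw
derives from the seeds recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import yaml

from . import corpus as corpus_mod
from . import neural_lm as nn
from . import probing as probing_mod
from . import simulation as sim
from .corpus import GrammarConfig, Grammar, generate_corpus, build_vocab, TAGSET
from .neural_lm import EncoderConfig, TrainConfig
from .stats import RegressionSpec, prune_random_effects, fit_beta_mixed, fit_linear_mixed
from .stimuli import PARADIGMS, generate_paradigm_items, load_items, save_items

logger = logging.getLogger(__name__)

DEFAULT_PARADIGMS = ("bock_cutting", "franck", "haskell", "humphreys", "parker_an", "wagers")

#: regression formulas per paradigm: (response, kind, fixed terms)
PARADIGM_FORMULAS = {
    "bock_cutting": ("error_rate", "probability",
                     ("attractor_match", "subject_number", "modifier",
                      "attractor_match:subject_number", "attractor_match:modifier")),
    "franck": ("error_rate", "probability",
               ("syntactic_match", "linear_match", "syntactic_match:linear_match")),
    "haskell": ("plural_rate", "probability", ("closer_number",)),
    "humphreys": ("plural_rate", "probability", ("preposition_bias",)),
    "parker_an": ("surprisal", "gaussian",
                  ("attractor_match", "grammaticality", "argument",
                   "attractor_match:grammaticality", "attractor_match:argument")),
    "wagers": ("surprisal", "gaussian",
               ("attractor_match", "grammaticality", "attractor_match:grammaticality")),
}


@dataclass
class RunConfig:
    """Full configuration of a toy replication run.

    Defaults mirror the reference setup (2-layer 650-unit LSTMs, 12
    epochs, 5 instances, the *is*/*are* candidate pair, the one-sample
    rule) except for the scale knobs a toy run must set explicitly.
    """

    grammar: GrammarConfig = field(default_factory=GrammarConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    n_sentences: int = 50_000
    n_heldout: int = 2_000
    paradigms: tuple[str, ...] = DEFAULT_PARADIGMS
    n_items: int = 24
    linking_rule: str = "one_sample"
    seed: int = 0
    out_dir: str = "runs/toy"
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(
            grammar=GrammarConfig(**raw.get("grammar", {})),
            encoder=EncoderConfig(**raw.get("encoder", {})),
            training=TrainConfig(**raw.get("training", {})),
            **{k: v for k, v in raw.items() if k not in ("grammar", "encoder", "training")},
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def analyze_paradigm(results, paradigm: str, prune: bool = False):
    """Fit the paradigm's registered regression; returns (fit, contrasts)."""
    response, kind, fixed = PARADIGM_FORMULAS[paradigm]
    spec = RegressionSpec(response, kind, fixed=fixed,
                          random_intercepts=("item", "instance"))
    data = results.dropna(subset=[response])
    if prune:
        maximal = dataclasses.replace(
            spec, random_slopes=tuple(("item", t) for t in fixed if ":" not in t))
        _, fit, _ = prune_random_effects(data, maximal)
    else:
        fit = fit_beta_mixed(data, spec) if kind == "probability" else \
            fit_linear_mixed(data, spec)
    contrasts = sim.asymmetry_contrasts(results)
    return fit, contrasts


def replicate_toy(config: RunConfig) -> dict:
    """Run the full pipeline at toy scale; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "warnings": [],
                      "version": _pkg_version()}
    stage_t0 = time.time()

    def done(stage):
        manifest["stages"][stage] = round(time.time() - stage_t0, 2)

    try:
        # 1. corpus
        full = generate_corpus(config.grammar, config.n_sentences + config.n_heldout)
        train_c, held = full[:config.n_sentences], full[config.n_sentences:]
        vocab = build_vocab(train_c)
        corpus_mod.write_corpus(train_c[:200], out / "corpus_sample")
        manifest["corpus"] = {
            "n_train": len(train_c), "n_heldout": len(held), "vocab_size": len(vocab),
            "sample_sha256": _sha256(out / "corpus_sample.txt"),
        }
        counts = corpus_mod.construction_counts(train_c)
        counts.to_csv(out / "construction_counts.csv")
        done("corpus")

        # 2. models
        stage_t0 = time.time()
        lm_cfg = dataclasses.replace(config.training, weight_word=1.0, weight_tag=0.0,
                                     seed=config.seed)
        mt_cfg = dataclasses.replace(config.training, seed=config.seed + 1000)
        lm_models, lm_traces = nn.train_instances(train_c, vocab, config.encoder, lm_cfg)
        mt_models, mt_traces = nn.train_instances(train_c, vocab, config.encoder, mt_cfg,
                                                  tagset=list(TAGSET))
        manifest["models"] = {
            "lm_only": [{"ppl": nn.perplexity(m, held),
                         "checksum": m.parameter_checksum()} for m in lm_models],
            "lm_ccg": [{"ppl": nn.perplexity(m, held),
                        "tag_accuracy": nn.supertag_accuracy(m, held)[0],
                        "checksum": m.parameter_checksum()} for m in mt_models],
            "unigram_ppl": nn.perplexity(nn.UnigramModel(train_c, vocab), held),
        }
        done("training")

        # 3. simulations + stats
        stage_t0 = time.time()
        grammar = Grammar(config.grammar)
        manifest["effects"] = {}
        for paradigm in config.paradigms:
            items = generate_paradigm_items(paradigm, grammar, config.n_items,
                                            seed=config.seed + hashable(paradigm))
            save_items(items, out / f"items_{paradigm}.csv")
            effects = {}
            for label, models in (("lm_only", lm_models), ("lm_ccg", mt_models)):
                if PARADIGMS[paradigm]["measure"] == "completion":
                    res = sim.run_production(models, items, rule=config.linking_rule)
                else:
                    res = sim.run_comprehension(models, items)
                res.drop(columns=[c for c in ("surprisals",) if c in res],
                         ).to_csv(out / f"trials_{paradigm}_{label}.csv", index=False)
                fit, contrasts = analyze_paradigm(res, paradigm)
                fit.summary().to_csv(out / f"coefficients_{paradigm}_{label}.csv", index=False)
                effects[label] = {name: eff.mean() for name, eff in contrasts.items()}
                if config.make_figures:
                    _effect_figure(contrasts, out / f"fig_{paradigm}_{label}.png")
            manifest["effects"][paradigm] = effects
        done("simulation")

        # 4. probing
        stage_t0 = time.time()
        probe_eval = held[:500]
        records, r, baseline = probing_mod.ablation_sweep(mt_models[0], probe_eval)
        import pandas as pd
        pd.DataFrame([dataclasses.asdict(rec) for rec in records]).to_csv(
            out / "ablation_sweep.csv", index=False)
        report = probing_mod.amnesic_report(mt_models[0], lm_models[0], probe_eval,
                                            train_corpus_for_probe=train_c[:3000],
                                            seed=config.seed)
        report.to_csv(out / "amnesic_report.csv", index=False)
        manifest["probing"] = {
            "ablation_loss_correlation": r,
            "ablation_baseline": baseline,
            "amnesic_report": report.to_dict(orient="records"),
        }
        done("probing")
    except Exception as e:  # noqa: BLE001 - abort with stage name, manifest written
        manifest["error"] = {"stage": _last_stage(manifest), "message": str(e)}
        _write_atomic(out / "manifest.json", json.dumps(manifest, indent=2, default=float))
        raise
    _write_atomic(out / "manifest.json", json.dumps(manifest, indent=2, default=float))
    return manifest


def _last_stage(manifest):
    order = ("corpus", "training", "simulation", "probing")
    for s in order:
        if s not in manifest["stages"]:
            return s
    return "finalize"


def hashable(name: str) -> int:
    import zlib
    return zlib.crc32(name.encode()) % 100_000


def _pkg_version() -> str:
    from . import __version__
    return __version__


def _effect_figure(contrasts, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(contrasts)
    fig, ax = plt.subplots(figsize=(1.5 + len(names), 3))
    means = [contrasts[n].mean() for n in names]
    errs = [contrasts[n].table["value"].std(ddof=1) / max(len(contrasts[n].table), 1) ** 0.5
            for n in names]
    ax.bar(range(len(names)), means, yerr=errs, color="#44709d")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xticks(range(len(names)), names, rotation=30, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli():
    """agreesim: neural-network simulations of agreement attraction."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@cli.command("generate-corpus")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--n", "n_sentences", type=int, required=True)
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_prefix", required=True)
def cli_generate_corpus(config_path, n_sentences, seed, out_prefix):
    """Generate a synthetic training corpus (text + supertags + annotations)."""
    kwargs = {}
    if config_path:
        with open(config_path) as f:
            kwargs = (yaml.safe_load(f) or {}).get("grammar", {})
    kwargs["seed"] = seed
    cfg = GrammarConfig(**kwargs)
    corp = generate_corpus(cfg, n_sentences)
    corpus_mod.write_corpus(corp, out_prefix)
    click.echo(corpus_mod.construction_counts(corp).to_string())


@cli.command("train")
@click.option("--corpus", "corpus_prefix", required=True)
@click.option("--arch", type=click.Choice(["srn", "lstm"]), default="lstm")
@click.option("--multitask", type=click.Choice(["on", "off"]), default="off")
@click.option("--epochs", type=int, default=12)
@click.option("--seed", type=int, default=0)
@click.option("--instances", type=int, default=5)
@click.option("--layers", type=int, default=2)
@click.option("--hidden", type=int, default=650)
@click.option("--embedding", type=int, default=650)
@click.option("--out", "out_dir", required=True)
def cli_train(corpus_prefix, arch, multitask, epochs, seed, instances,
              layers, hidden, embedding, out_dir):
    """Train language-model instances on a generated corpus."""
    corp = corpus_mod.read_corpus(corpus_prefix)
    vocab = build_vocab(corp)
    enc = EncoderConfig(arch, layers, hidden, embedding)
    tc = TrainConfig(epochs=epochs, seed=seed, n_instances=instances,
                     weight_word=1.0 if multitask == "off" else 0.5,
                     weight_tag=0.0 if multitask == "off" else 0.5)
    tagset = list(TAGSET) if multitask == "on" else None
    models, traces = nn.train_instances(corp, vocab, enc, tc, tagset=tagset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, m in enumerate(models):
        nn.save_model(m, out / f"instance_{k}.npz")
    (out / "traces.json").write_text(json.dumps(traces, indent=2, default=float))
    click.echo(f"saved {len(models)} instances to {out}")


@cli.command("simulate")
@click.option("--models", "model_dir", required=True)
@click.option("--items", "items_path", required=True, type=click.Path(exists=True))
@click.option("--linking", default="one_sample",
              type=click.Choice(["one_sample", "max_prob", "n_sample"]))
@click.option("--n-samples", type=int, default=None)
@click.option("--out", "out_dir", required=True)
def cli_simulate(model_dir, items_path, linking, n_samples, out_dir):
    """Run production/comprehension simulations over saved models."""
    models = [nn.load_model(p) for p in sorted(Path(model_dir).glob("instance_*.npz"))]
    items = load_items(items_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completion = [it for it in items if it.measure == "completion"]
    reading = [it for it in items if it.measure == "reading"]
    if completion:
        df = sim.run_production(models, completion, rule=linking, n=n_samples)
        df.to_csv(out / "production_trials.csv", index=False)
    if reading:
        df = sim.run_comprehension(models, reading)
        df.drop(columns=["surprisals"]).to_csv(out / "reading_trials.csv", index=False)
    click.echo(f"wrote trial tables to {out}")


@cli.command("analyze")
@click.option("--trials", "trials_path", required=True, type=click.Path(exists=True))
@click.option("--paradigm", required=True, type=click.Choice(sorted(PARADIGMS)))
@click.option("--prune/--no-prune", default=False)
@click.option("--out", "out_path", required=True)
def cli_analyze(trials_path, paradigm, prune, out_path):
    """Fit the paradigm's mixed-effects analysis on a trial table."""
    import pandas as pd
    results = pd.read_csv(trials_path)
    fit, contrasts = analyze_paradigm(results, paradigm, prune=prune)
    fit.summary().to_csv(out_path, index=False)
    for name, eff in contrasts.items():
        click.echo(f"{name}: {eff.mean():+.4f}")


@cli.command("probe")
@click.argument("mode", type=click.Choice(["ablate", "amnesic"]))
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--lm-only-model", "lm_only_path", default=None)
@click.option("--corpus", "corpus_prefix", required=True)
@click.option("--out", "out_path", required=True)
def cli_probe(mode, model_path, lm_only_path, corpus_prefix, out_path):
    """Unit-ablation sweep or amnesic (nullspace projection) report."""
    import pandas as pd
    model = nn.load_model(model_path)
    corp = corpus_mod.read_corpus(corpus_prefix)
    if mode == "ablate":
        records, r, baseline = probing_mod.ablation_sweep(model, corp)
        pd.DataFrame([dataclasses.asdict(rec) for rec in records]).to_csv(out_path, index=False)
        click.echo(f"loss correlation r={r:.3f}; baseline={baseline}")
    else:
        if lm_only_path is None:
            raise click.UsageError("amnesic mode needs --lm-only-model")
        lm_only = nn.load_model(lm_only_path)
        report = probing_mod.amnesic_report(model, lm_only, corp)
        report.to_csv(out_path, index=False)
        click.echo(report.to_string(index=False))


@cli.command("replicate-toy")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", default=None)
@click.option("--seed", type=int, default=None)
def cli_replicate_toy(config_path, out_dir, seed):
    """End-to-end toy replication; writes effect tables and a manifest."""
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig(
        n_sentences=20_000, n_items=12,
        training=TrainConfig(epochs=2, n_instances=2, batch_size=64),
        encoder=EncoderConfig("lstm", 2, 64, 64),
    )
    if out_dir:
        cfg.out_dir = out_dir
    if seed is not None:
        cfg.seed = seed
    manifest = replicate_toy(cfg)
    click.echo(json.dumps(manifest["effects"], indent=2, default=float))


@cli.command("report")
@click.option("--run", "run_dir", required=True, type=click.Path(exists=True))
def cli_report(run_dir):
    """Summarize a finished run from its manifest."""
    manifest = json.loads((Path(run_dir) / "manifest.json").read_text())
    click.echo(json.dumps({k: manifest[k] for k in ("stages", "effects", "probing")
                           if k in manifest}, indent=2, default=float))


if __name__ == "__main__":
    cli()
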