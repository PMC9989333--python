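"""Experiment drivers, seed management, configuration and the CLI.

Two packaged experiments run end-to-end on synthetic sequences:

* **broad-scale**: simulate whole-population chromosomes under a demographic
  model, compute each population's private-SNP spectrum, and measure how the
  spectrum of subsamples (drawn with replacement over a grid of sizes)
  deviates from the whole population (total-difference convergence curves).
* **fine-scale**: the two-scenario two-proportion Z power surface for a
  single-mutation-type fold shift over grids of folds and sample sizes.

Defaults are desk-scale (tens of replicates, 100 kb chromosomes); the
original cluster-scale settings (1,000 replicates of a 46.7 Mb chromosome,
100 x 1 Mb regions) are reachable purely through configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import click
import numpy as np
import pandas as pd
import yaml

from . import demography, mutation_model, power as power_mod, sequence, simulator, spectra, subsampling
from .demography import PopulationModel, build_basic_model, load_model, shipped_model_path
from .mutation_model import MutationType, build_uniform_matrix, load_matrix, normalize_overall_rate, shipped_matrix_path, write_matrix
from .sequence import HUMAN_LIKE_COMPOSITION, AncestralSequence, generate_sequence, load_fasta, write_fasta
from .simulator import simulate_dataset
from .spectra import STRANDED_192, compute_spectrum, private_segregating, write_spectrum
from .subsampling import SamplingScheme, convergence_curve, default_scheme

__all__ = ["ExperimentConfig", "seed_stream", "run_broad_scale", "run_fine_scale", "cli"]

log = logging.getLogger("mutspectra")

_SEED_MOD = 2**31


def seed_stream(master_seed, *labels) -> int:
    """Deterministic child seed for a labelled piece of work.

    Hashes the master seed together with the labels (blake2b), so every
    (experiment, replicate, size, scenario, ...) cell gets an independent,
    reproducible, order-independent stream.  Result is < 2**31.
    """
    payload = repr((master_seed,) + tuple(labels)).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % _SEED_MOD


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; loadable from YAML."""

    model: str = "basic:constant"  # "basic:<variant>", shipped name, or a path
    sequence_length: int = 100_000
    sequence_composition: Sequence[float] = HUMAN_LIKE_COMPOSITION
    sequence_fasta: Optional[str] = None
    matrix: str = "uniform"  # shipped matrix name or a path
    mu: float = power_mod.DEFAULT_MU
    window_length: int = 10_000
    replicates: int = 20
    whole_population_size: int = 100  # diploids sampled as "the whole population"
    scheme_sizes: Sequence[int] = (5, 10, 20, 40, 80, 160)
    scheme_replicates: int = 5
    populations: Optional[Sequence[str]] = None  # focal pops; default: all sampled
    # fine-scale settings
    pair: Optional[Sequence[str]] = None
    mutation_type: str = "TCC>T"
    folds: Sequence[float] = (0.9, 1.2, 1.5, 1.725, 2.0)
    sizes: Sequence[int] = (2, 5, 10, 25, 50)
    region_length: int = 1_000_000
    alpha: float = 0.05
    space: str = "collapsed96"
    mode: str = "expected"
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, (tuple, list)) else v) for k, v in vars(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.blake2b(payload.encode(), digest_size=6).hexdigest()

    # -- resource resolution -------------------------------------------------

    def resolve_model(self) -> PopulationModel:
        if self.model.startswith("basic:"):
            return build_basic_model(self.model.split(":", 1)[1])
        if self.model in ("human", "chimpanzee"):
            return load_model(shipped_model_path(self.model))
        return load_model(self.model)

    def resolve_sequence(self, seed: int) -> AncestralSequence:
        if self.sequence_fasta:
            seq = load_fasta(self.sequence_fasta)
            if seq.n_missing:
                seq = sequence.impute_missing(seq, seed=seed_stream(seed, "impute"))
            return seq
        return generate_sequence(self.sequence_length, self.sequence_composition, seed=seed_stream(seed, "sequence"))

    def resolve_matrix(self):
        if self.matrix == "uniform":
            return build_uniform_matrix()
        try:
            return load_matrix(shipped_matrix_path(self.matrix))
        except FileNotFoundError:
            return load_matrix(self.matrix)

    def parse_type(self) -> MutationType:
        tri, derived = self.mutation_type.split(">")
        return MutationType(tri, derived)


def _header_lines(cfg: ExperimentConfig) -> list:
    return [f"config_hash {cfg.config_hash()}", f"master_seed {cfg.master_seed}"]


def run_broad_scale(cfg: ExperimentConfig, outdir: Union[str, Path]) -> dict:
    """Broad-scale convergence experiment; one TSV of convergence curves per
    focal population (replicates stacked), plus the whole-population spectra."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = cfg.resolve_model()
    seq = cfg.resolve_sequence(cfg.master_seed)
    matrix = normalize_overall_rate(cfg.resolve_matrix(), seq, cfg.mu)
    sampled = list(cfg.populations or model.population_ids)
    samples = {p: 2 * cfg.whole_population_size for p in model.population_ids}
    scheme = SamplingScheme(tuple(cfg.scheme_sizes), cfg.scheme_replicates)

    outputs: dict = {}
    frames: dict = {p: [] for p in sampled}
    for rep in range(cfg.replicates):
        t0 = time.perf_counter()
        table = simulate_dataset(
            model, seq, matrix, samples,
            window_length=cfg.window_length,
            seed=seed_stream(cfg.master_seed, "broad", rep),
        )
        log.info("broad replicate %d: %d variants in %.1fs", rep, len(table), time.perf_counter() - t0)
        for popid in sampled:
            curve = convergence_curve(
                table, popid, scheme,
                seed=seed_stream(cfg.master_seed, "broad", rep, popid),
            )
            curve.insert(0, "replicate_chromosome", rep)
            frames[popid].append(curve)
            if rep == 0:
                spec = compute_spectrum(private_segregating(table, popid))
                spath = outdir / f"spectrum_{popid}.tsv"
                write_spectrum(spec, spath)
                outputs[f"spectrum_{popid}"] = spath
    for popid in sampled:
        df = pd.concat(frames[popid], ignore_index=True)
        path = outdir / f"convergence_{popid}.tsv"
        with open(path, "w") as fh:
            for line in _header_lines(cfg):
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)
        outputs[f"convergence_{popid}"] = path
    return outputs


def run_fine_scale(cfg: ExperimentConfig, outdir: Union[str, Path]) -> dict:
    """Fine-scale power surface for the configured population pair."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = cfg.resolve_model()
    if cfg.pair is None:
        raise ValueError("fine-scale experiment needs a 'pair' of population ids")
    pair = tuple(cfg.pair)
    surface = power_mod.power_surface(
        model, pair, cfg.parse_type(),
        folds=list(cfg.folds), sizes=list(cfg.sizes),
        region_length=cfg.region_length, window_length=cfg.window_length,
        replicates=cfg.replicates, alpha=cfg.alpha,
        seed=seed_stream(cfg.master_seed, "fine"),
        space=cfg.space, mode=cfg.mode,
    )
    path = outdir / f"power_{pair[0]}_{pair[1]}.tsv"
    with open(path, "w") as fh:
        for line in _header_lines(cfg):
            fh.write(f"# {line}\n")
        surface.to_csv(fh, sep="\t", index=False)
    return {"power": path, "surface": surface}


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable progress logging.")
def cli(verbose):
    """Simulate trinucleotide mutational spectra and analyse sample-size and
    demography effects."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=False)
@click.option("--seed", type=int, default=None, help="Override the config's master seed.")
@click.option("--out", type=click.Path(), required=True)
def simulate(config_path, seed, out):
    """Simulate one dataset and write it as TSV (+VCF)."""
    cfg = ExperimentConfig.from_yaml(config_path) if config_path else ExperimentConfig()
    if seed is not None:
        cfg.master_seed = seed
    model = cfg.resolve_model()
    seq = cfg.resolve_sequence(cfg.master_seed)
    matrix = normalize_overall_rate(cfg.resolve_matrix(), seq, cfg.mu)
    samples = {p: 2 * cfg.whole_population_size for p in model.population_ids}
    table = simulate_dataset(model, seq, matrix, samples, cfg.window_length, seed=seed_stream(cfg.master_seed, "simulate"))
    out = Path(out)
    table.to_tsv(out, header_lines=_header_lines(cfg))
    table.to_vcf(out.with_suffix(".vcf"), contig=seq.label, contig_length=len(seq))
    click.echo(f"wrote {len(table)} variants to {out}")


@cli.command()
@click.option("--variants", type=click.Path(exists=True), required=True, help="VariantTable TSV.")
@click.option("--population", required=True)
@click.option("--space", type=click.Choice(["stranded192", "collapsed96"]), default="stranded192")
@click.option("--out", type=click.Path(), required=True)
def spectrum(variants, population, space, out):
    """Private-SNP mutational spectrum of one population."""
    from .variants import VariantTable

    table = VariantTable.from_tsv(variants)
    spec = compute_spectrum(private_segregating(table, population), space=space)
    write_spectrum(spec, out)
    click.echo(f"wrote {space} spectrum ({spec.total} private SNPs) to {out}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=False)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def converge(config_path, seed, out):
    """Run the broad-scale subsampling convergence experiment."""
    cfg = ExperimentConfig.from_yaml(config_path) if config_path else ExperimentConfig()
    if seed is not None:
        cfg.master_seed = seed
    outputs = run_broad_scale(cfg, out)
    for name, path in outputs.items():
        click.echo(f"{name}: {path}")


@cli.command(name="power")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def power_cmd(config_path, seed, out):
    """Run the fine-scale power-surface experiment."""
    cfg = ExperimentConfig.from_yaml(config_path)
    if seed is not None:
        cfg.master_seed = seed
    outputs = run_fine_scale(cfg, out)
    click.echo(f"power surface: {outputs['power']}")


@cli.command()
@click.option("--out", type=click.Path(), required=True)
@click.option("--length", type=int, default=100_000)
@click.option("--seed", type=int, default=0)
def fixtures(out, length, seed):
    """Emit synthetic sequences plus the shipped model/matrix files."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for name, comp in (("uniform", (0.25, 0.25, 0.25, 0.25)), ("hominid", HUMAN_LIKE_COMPOSITION)):
        seq = generate_sequence(length, comp, seed=seed_stream(seed, "fixture", name), label=f"synthetic_{name}")
        write_fasta(seq, out / f"synthetic_{name}.fasta")
    for model_name in ("human", "chimpanzee"):
        (out / f"model_{model_name}.yaml").write_text(shipped_model_path(model_name).read_text())
    for matrix_name in ("uniform", "human_like_synthetic"):
        (out / f"matrix_{matrix_name}.tsv").write_text(shipped_matrix_path(matrix_name).read_text())
    click.echo(f"fixtures written to {out}")


if __name__ == "__main__":  # pragma: no cover
    cli()
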