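"""End-to-end orchestration: estimate -> screen -> select -> PGLS.

A run consumes either real input files (the three study tables plus a
Newick tree) or a simulation block, produces per-marker diversity
estimates, the univariate screening table, stepwise model-selection paths
with the parsimony rule applied, and PGLS confirmations of the selected
models, and records everything in a manifest with content digests so a
re-run on identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__ as _version
from .comparative import pgls_fit
from .dataio import (read_factors_table, read_msat_table, read_mtdna_table,
                     write_estimates, write_factors_table, write_msat_table,
                     write_mtdna_table)
from .design import factor_frame
from .effects import effects_frame, screen_all
from .errors import CetadivError, ValidationError
from .msat import estimate_relative_diversity
from .mtdna import aggregate_pi
from .records import SCOPE_TO_MIC_MARKER, SCOPE_TO_PI_MARKER, DiversityEstimate
from .selection import parsimony_select, stepwise_aic, fit_linear_model
from .simulate import SimulationConfig, simulate_study
from .tree import PhyloTree, read_newick

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_full_analysis",
           "exclude_matrilineal_variant", "DEFAULT_CANDIDATE_POOL"]

#: Default stepwise candidate pool: every factor except the encephalization
#: quotient and the IUCN population trend (they shrink the species sample
#: too much) and the Mysticete-only breeding strategy.
DEFAULT_CANDIDATE_POOL = (
    "population_size", "latitudinal_range", "max_length", "generation_time",
    "lifespan", "whaling1", "whaling2", "suborder", "family", "hemisphere",
    "ocean1", "ocean2", "habitat", "temperature", "group_size",
    "social_structure",
)


@dataclass
class PipelineConfig:
    """Inputs and knobs for one full analysis run."""

    out_dir: Path
    # file inputs (omit to skip the stage or to simulate instead)
    msat_regional: Optional[Path] = None
    msat_rangewide: Optional[Path] = None
    mtdna_regional: Optional[Path] = None
    mtdna_rangewide: Optional[Path] = None
    factors: Optional[Path] = None
    tree: Optional[Path] = None
    simulation: Optional[SimulationConfig] = None
    candidate_pool: Sequence[str] = DEFAULT_CANDIDATE_POOL
    pgls_structure: str = "lambda"
    parsimony_delta: float = 5.0
    exclude_matrilineal: bool = False
    seed: int = 0


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    input_digests: Dict[str, str]
    output_digests: Dict[str, str]
    stage_counts: Dict[str, int]
    warnings: List[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True,
                      default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig, manifest: RunManifest):
    """Read or simulate the raw inputs; returns a bundle-like dict."""
    bundle: Dict[str, object] = {}
    if config.simulation is not None:
        sim = simulate_study(config.simulation)
        bundle.update(sim)
        out = Path(config.out_dir) / "inputs"
        out.mkdir(parents=True, exist_ok=True)
        sim["tree"].write(out / "tree.nwk")
        write_factors_table(sim["factors"], out / "factors.csv")
        for scope in ("regional", "rangewide"):
            write_msat_table(sim[f"msat_{scope}"], out / f"msat_{scope}.csv")
            write_mtdna_table(sim[f"mtdna_{scope}"], out / f"mtdna_{scope}.csv")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(sim["truth"], fh, indent=2, sort_keys=True)
        for p in sorted(out.iterdir()):
            manifest.input_digests[p.name] = _sha256(p)
        return bundle
    if config.factors is None or config.tree is None:
        raise ValidationError(
            "config must name a factors table and a tree, or a simulation block")
    bundle["factors"] = read_factors_table(config.factors)
    bundle["tree"] = read_newick(config.tree)
    manifest.input_digests["factors"] = _sha256(config.factors)
    manifest.input_digests["tree"] = _sha256(config.tree)
    for scope in ("regional", "rangewide"):
        for kind, reader in (("msat", read_msat_table),
                             ("mtdna", read_mtdna_table)):
            path = getattr(config, f"{kind}_{scope}")
            if path is not None:
                bundle[f"{kind}_{scope}"] = reader(path)
                manifest.input_digests[f"{kind}_{scope}"] = _sha256(path)
            else:
                logger.info("no %s_%s table; stage will be skipped", kind, scope)
    return bundle


def _estimate_stage(bundle, manifest, out_dir: Path
                    ) -> Tuple[List[DiversityEstimate], Dict[str, dict]]:
    estimates: List[DiversityEstimate] = []
    sidecar: Dict[str, dict] = {}
    for scope in ("regional", "rangewide"):
        msat = bundle.get(f"msat_{scope}")
        if msat:
            est, correction, mixed = estimate_relative_diversity(
                msat, scope=scope, return_fits=True)
            estimates.extend(est)
            marker = SCOPE_TO_MIC_MARKER[scope]
            manifest.stage_counts[f"n_species_{marker}"] = len(est)
            if correction is not None:
                sidecar[marker] = {
                    "mu": correction.mu,
                    "ascertainment_effect": mixed.ascertainment_effect,
                    "locus_variance": mixed.locus_variance,
                    "residual_variance": mixed.residual_variance,
                    "converged": mixed.converged,
                    "n_records": mixed.n_records,
                }
        mtdna = bundle.get(f"mtdna_{scope}")
        if mtdna:
            est = aggregate_pi(mtdna, scope=scope)
            estimates.extend(est)
            marker = SCOPE_TO_PI_MARKER[scope]
            manifest.stage_counts[f"n_species_{marker}"] = len(est)
    write_estimates(estimates, out_dir / "diversity_estimates.csv")
    with open(out_dir / "estimation_fits.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return estimates, sidecar


def _selection_stage(estimates, frame, tree, config: PipelineConfig,
                     manifest, out_dir: Path) -> Dict[str, dict]:
    """Stepwise AIC per marker, parsimony rule, then PGLS confirmation."""
    by_marker: Dict[str, Dict[str, float]] = {}
    for e in estimates:
        by_marker.setdefault(e.marker, {})[e.species_id] = e.value
    results: Dict[str, dict] = {}
    rows = []
    for marker, values in sorted(by_marker.items()):
        response = pd.Series(values, dtype=float)
        response = response[response.index.isin(frame.index)]
        pool = [t for t in config.candidate_pool if t in frame.columns]
        try:
            step = stepwise_aic(response, pool, frame)
        except (CetadivError, ValueError) as exc:
            manifest.warnings.append(f"stepwise failed for {marker}: {exc}")
            continue
        # candidate models for the parsimony rule: every model visited on
        # the path (refit on the frozen species set), plus the null model
        sub = frame.loc[list(step.species_set)]
        resp = response.loc[list(step.species_set)]
        seen: Dict[Tuple[str, ...], object] = {}
        terms: List[str] = []
        seen[()] = fit_linear_model(resp, (), sub)
        for action, term, _aic in step.path:
            if action == "add":
                terms.append(term)
            elif action == "drop":
                terms.remove(term)
            else:
                continue
            seen[tuple(terms)] = fit_linear_model(resp, tuple(terms), sub)
        selected = parsimony_select(list(seen.values()),
                                    delta=config.parsimony_delta)
        entry = {
            "marker": marker,
            "n": selected.n,
            "stepwise_terms": list(step.selected.terms),
            "selected_terms": list(selected.terms),
            "aic_null": seen[()].aic,
            "aic_selected": selected.aic,
            "path": [{"action": a, "term": t, "aic": v}
                     for a, t, v in step.path],
        }
        for fit in seen.values():
            rows.append({"marker": marker, "terms": "+".join(fit.terms) or "1",
                         "n": fit.n, "aic": fit.aic})
        if selected.terms and tree is not None:
            try:
                g = pgls_fit(tree, values, frame, list(selected.terms),
                             structure=config.pgls_structure)
                entry["pgls"] = {
                    "structure": g.structure,
                    "structure_param": g.structure_param,
                    "n": g.n,
                    "term_F": g.term_F,
                    "term_p": g.term_p,
                    "coefficients": g.coefficients,
                    "log_likelihood": g.log_likelihood,
                }
            except (CetadivError, ValueError) as exc:
                manifest.warnings.append(f"PGLS failed for {marker}: {exc}")
        results[marker] = entry
    pd.DataFrame(rows, columns=["marker", "terms", "n", "aic"]).to_csv(
        out_dir / "model_selection.csv", index=False)
    with open(out_dir / "selected_models.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results


def run_full_analysis(config: PipelineConfig) -> RunManifest:
    """Run every stage the configured inputs support; write all outputs.

    Stages with no input are skipped with a logged reason; a stage
    failure aborts the run with the stage named, leaving earlier outputs
    in place.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config),
                           seed=config.seed, version=_version,
                           input_digests={}, output_digests={},
                           stage_counts={})
    stage = "load_inputs"
    try:
        bundle = _load_inputs(config, manifest)
        factors = bundle["factors"]
        tree: Optional[PhyloTree] = bundle.get("tree")
        frame = factor_frame(factors)
        if config.exclude_matrilineal:
            keep = frame.index[frame["social_structure"] != "Matrilineal"]
            dropped = sorted(set(frame.index) - set(keep))
            frame = frame.loc[keep]
            if tree is not None:
                tree = tree.prune([t for t in tree.tip_labels if t in set(keep)])
            manifest.stage_counts["n_matrilineal_excluded"] = len(dropped)
        manifest.stage_counts["n_species_factors"] = len(frame)

        stage = "estimate"
        estimates, _ = _estimate_stage(bundle, manifest, out_dir)
        if config.exclude_matrilineal:
            estimates = [e for e in estimates if e.species_id in set(frame.index)]

        stage = "screen"
        screened = screen_all(factors={s: factors[s] for s in frame.index},
                              estimates=estimates, tree=tree)
        effects_frame(screened).to_csv(out_dir / "screening.csv", index=False)
        manifest.stage_counts["n_screen_rows"] = len(screened)

        stage = "select"
        _selection_stage(estimates, frame, tree, config, manifest, out_dir)
    except CetadivError as exc:
        raise CetadivError(f"stage {stage!r} failed: {exc}") from exc

    for p in sorted(out_dir.glob("*.csv")) + sorted(out_dir.glob("*.json")):
        if p.name == "manifest.json":  # a prior run's manifest is not output
            continue
        manifest.output_digests[p.name] = _sha256(p)
    manifest.write(out_dir / "manifest.json")
    return manifest


def exclude_matrilineal_variant(config: PipelineConfig) -> RunManifest:
    """Re-run the full analysis with matrilineal species dropped.

    Outputs land in ``<out_dir>/no_matrilineal`` so the variant never
    overwrites the main run.
    """
    variant = dataclasses.replace(
        config, exclude_matrilineal=True,
        out_dir=Path(config.out_dir) / "no_matrilineal")
    return run_full_analysis(variant)
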