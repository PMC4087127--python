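"""End-to-end pipeline glue: config-driven runs with a provenance manifest.

A run executes (optionally) data simulation, network reconstruction,
consensus building, rule conversion, attractor panels, an optional edgetic
scan and the drug-effect statistics, writing every stage output plus a YAML
manifest with the echoed configuration, derived seeds, file digests and
stage timings.  A single base seed deterministically expands to per-stage
and per-chain seeds, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boolean_sim import edgetic_scan, network_to_rules, simulate_drug_panel, write_rules
from .consensus import (
    greedy_augment,
    loo_consensus,
    observed_endpoint_from_data,
)
from .inhib_mcmc import MCMCConfig, gelman_rubin, run_chains, write_chain_results
from .likelihood_hmm import optimize_states, read_tidy_table, write_tidy_table
from .model_core import (
    PriorSpec,
    SignalingNetwork,
    StructureConstraints,
    read_edge_list,
    read_roster,
    write_edge_list,
)
from .stats_effects import drug_effect_test, optimal_treatment
from .synthetic_data import (
    GeneratorSpec,
    default_emission,
    default_longterm_design,
    default_shortterm_design,
    example_truth_network,
    generate_dataset,
)

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    version: str
    base_seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # name -> {path, sha256}
    timings: dict = field(default_factory=dict)   # stage -> seconds
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "base_seed": self.base_seed,
            "config": self.config,
            "stage_seeds": self.stage_seeds,
            "outputs": self.outputs,
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
            "status": self.status,
        }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(config: dict, key: str):
    if key not in config:
        raise KeyError(f"pipeline config missing required key {key!r}")
    return config[key]


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config_path) -> RunManifest:
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    out_dir = Path(_require(config, "out_dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    base_seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, version=__version__, base_seed=base_seed)

    def record(name: str, path: Path):
        manifest.outputs[name] = {"path": str(path), "sha256": _digest(path)}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
            def __exit__(self, *exc):
                manifest.timings[stage] = time.perf_counter() - self.t0
        return _T()

    try:
        # --- inputs / simulation -----------------------------------------
        if "simulate" in config:
            sim = config["simulate"]
            design = (default_shortterm_design() if sim.get("design", "short")
                      == "short" else default_longterm_design())
            truth = example_truth_network()
            if "truth_edges" in sim:
                roster = read_roster(_require(sim, "roster"))
                truth = read_edge_list(sim["truth_edges"], roster)
            seed = _stage_seed(base_seed, "simulate")
            manifest.stage_seeds["simulate"] = seed
            spec = GeneratorSpec(
                truth, design,
                default_emission(len(truth.roster.proteins)),
                sim.get("schedule", "even"), seed,
            )
            with timed("simulate"):
                data, _truth_assign = generate_dataset(spec)
            data_path = out_dir / "data.tsv"
            write_tidy_table(data, data_path)
            record("data", data_path)
            roster = truth.roster
        else:
            roster = read_roster(_require(config, "roster"))
            data = read_tidy_table(_require(config, "data"), roster,
                                   config.get("time_unit", "min"))

        prior_cfg = config.get("prior", {})
        if "edges" in prior_cfg:
            prior_net = read_edge_list(prior_cfg["edges"], roster)
        else:
            prior_net = SignalingNetwork.empty(roster)
        prior = PriorSpec.from_network(
            prior_net, prior_cfg.get("lambda", 0.0001), prior_cfg.get("gamma", 1.0)
        )

        # --- reconstruction ----------------------------------------------
        mc = config.get("mcmc", {})
        mcmc_config = MCMCConfig(
            prior=prior,
            iterations=int(mc.get("iterations", 50000)),
            burn_in=int(mc.get("burn_in", mc.get("iterations", 50000) // 2)),
            chains=int(mc.get("chains", 10)),
            seed=_stage_seed(base_seed, "reconstruct"),
            constraints=StructureConstraints(
                max_indegree=int(mc.get("max_indegree", 4))
            ),
        )
        manifest.stage_seeds["reconstruct"] = mcmc_config.seed
        with timed("reconstruct"):
            chains = run_chains(data, mcmc_config)
        chains_dir = out_dir / "chains"
        write_chain_results(chains, mcmc_config, chains_dir)
        record("chains_manifest", chains_dir / "manifest.yaml")
        traces = [c.log_posterior_trace[mcmc_config.burn_in:] for c in chains
                  if c.status == "ok"]
        gr = gelman_rubin(traces)
        manifest.outputs["gelman_psrf"] = {"value": gr.psrf,
                                           "converged": gr.converged}

        # --- consensus + augmentation ------------------------------------
        alpha = float(config.get("consensus", {}).get("alpha", 0.05))
        with timed("consensus"):
            cons = loo_consensus([c for c in chains if c.status == "ok"],
                                 alpha, mcmc_config.constraints)
            opt = optimize_states(prior_net, data)
            observed = observed_endpoint_from_data(data, opt.emission)
            final_net = greedy_augment(
                prior_net, cons, data, observed, mcmc_config.constraints,
                allow_deletions=bool(config.get("consensus", {})
                                     .get("allow_deletions", False)),
            )
        cons_path = out_dir / "consensus_edges.tsv"
        cons.edges.to_csv(cons_path, sep="\t", index=False)
        record("consensus_edges", cons_path)
        net_path = out_dir / "final_network.tsv"
        write_edge_list(final_net, net_path)
        record("final_network", net_path)

        # --- rules + attractors ------------------------------------------
        inputs = list(roster.perturbations)
        rules = network_to_rules(final_net, inputs)
        rules_path = out_dir / "network.rules"
        write_rules(rules, rules_path)
        record("rules", rules_path)

        att_cfg = config.get("attractors", {})
        drugs = att_cfg.get("drugs",
                            [n for n in roster.names if roster.roles[n] == "drug"])
        stimuli = att_cfg.get(
            "stimuli", [n for n in roster.names if roster.roles[n] == "stimulus"])
        readouts = att_cfg.get("readouts", list(roster.proteins))
        with timed("attractors"):
            panel = simulate_drug_panel(rules, drugs, stimuli, readouts)
        panel_path = out_dir / "attractor_panel.tsv"
        panel.to_csv(panel_path, sep="\t", index=False)
        record("attractor_panel", panel_path)

        if "edgetic" in config:
            ecfg = config["edgetic"]
            with timed("edgetic"):
                report = edgetic_scan(
                    final_net, _require(ecfg, "target"),
                    _require(ecfg, "parents"), drugs, stimuli,
                    ecfg.get("readouts", [ecfg["target"]]),
                )
            epath = out_dir / "edgetic_report.tsv"
            report.to_csv(epath, sep="\t", index=False)
            record("edgetic_report", epath)

        # --- drug-effect statistics --------------------------------------
        with timed("drugstats"):
            stats_rows = _drug_stats(data)
        stats_path = out_dir / "drug_effects.tsv"
        stats_rows.to_csv(stats_path, sep="\t", index=False)
        record("drug_effects", stats_path)
    except Exception:
        manifest.status = "failed"
        _write_manifest(manifest, out_dir)
        raise
    _write_manifest(manifest, out_dir)
    return manifest


def _drug_stats(data) -> pd.DataFrame:
    """Per (protein, stimulus context, drug set): the two-stage test against
    the matching drug-free condition."""
    design = data.design
    final_time = design.timepoints[-1]
    by_stim: dict[frozenset, int] = {}
    for c, (s, d) in enumerate(design.conditions):
        if not d:
            by_stim[s] = c
    rows, results_by_protein = [], {}
    for c, (s, d) in enumerate(design.conditions):
        if not d or s not in by_stim:
            continue
        c0 = by_stim[s]
        for p_idx, prot in enumerate(data.roster.proteins):
            def _frame(ci):
                recs = []
                for ti, t in enumerate(design.timepoints):
                    for r in range(data.values.shape[3]):
                        v = data.values[p_idx, ci, ti, r]
                        if np.isfinite(v):
                            recs.append((t, r + 1, v))
                return pd.DataFrame(recs, columns=["time", "replicate", "value"])

            treatment = "+".join(sorted(d))
            res = drug_effect_test(_frame(c), _frame(c0), final_time,
                                   protein=prot, treatment=treatment)
            key = (prot, "+".join(sorted(s)))
            results_by_protein.setdefault(key, []).append(res)
            rows.append({
                "protein": prot, "stimuli": "+".join(sorted(s)),
                "treatment": treatment,
                "interaction_p": res.interaction_p,
                "endpoint_p": res.endpoint_p,
                "efficient": res.efficient,
            })
    df = pd.DataFrame(rows)
    if not df.empty:
        best = {k: optimal_treatment(v) for k, v in results_by_protein.items()}
        df["optimal"] = [
            best[(r.protein, r.stimuli)] == r.treatment
            if best[(r.protein, r.stimuli)] else False
            for r in df.itertuples()
        ]
    return df


def _write_manifest(manifest: RunManifest, out_dir: Path) -> None:
    with open(out_dir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)
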