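"""End-to-end orchestration: simulate -> scan -> annotate -> profile ->
validate -> network, with a hashed output manifest.

A run is driven by a plain YAML config; rerunning with the same config
(and seed) reproduces every output file byte for byte, which the
manifest's content hashes make checkable.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import yaml

from . import annotate as ann
from . import io as msio
from . import network as net
from . import profiles as prof
from . import validate as val
from .models import MimicRuleParams, MiRNA
from .scan import ScanParams, scan_transcriptome
from .simulate import SimConfig, generate, score_pipeline_against_truth

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["simulate", "scan", "annotate", "profile", "validate", "network"],
    "simulate": {},
    "scan": {"gu_counts_as_mismatch": True, "max_middle_mismatches": None},
    "validate": {"min_reads_same_5p": 3, "prominence_fraction": 1.0,
                 "species_mode": False, "max_score": 3.0},
    "inputs": {},  # mirnas/transcripts/structures/degradome paths; used when
                   # the simulate stage is disabled
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(str(path_or_dict)) as fh:
            user = yaml.safe_load(fh) or {}
    config = {k: (v.copy() if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config, out_dir: str | os.PathLike) -> dict:
    """Run the configured stages; returns the manifest (also written as JSON).

    Stage outputs land in fixed subdirectories of ``out_dir``; the
    manifest maps every output file to its SHA-256 content hash.
    """
    config = load_config(config)
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    stages = config["stages"]
    manifest: dict = {"seed": config["seed"], "stages": {}}

    def record(stage: str, *paths: str) -> None:
        block = manifest["stages"].setdefault(stage, {})
        for p in paths:
            block[os.path.relpath(p, out_dir)] = _sha256(p)

    # --- inputs: simulated or loaded from configured paths
    if "simulate" in stages:
        sim_cfg = SimConfig(seed=config["seed"], **config["simulate"])
        sim = generate(sim_cfg)
        data_dir = os.path.join(out_dir, "data")
        paths = sim.write(data_dir)
        record("simulate", *paths.values())
        mirnas, transcripts, libraries = sim.mirnas, sim.transcripts, sim.libraries
        truth = sim.truth
    else:
        inputs = config["inputs"]
        for key in ("mirnas", "transcripts"):
            if key not in inputs or not os.path.exists(inputs[key]):
                raise FileNotFoundError(
                    f"input '{key}' missing or not found "
                    f"({inputs.get(key, '<unset>')}); required when the "
                    f"simulate stage is disabled"
                )
        mirnas = [MiRNA(id=i, sequence=s) for i, s in msio.read_fasta(inputs["mirnas"])]
        structures = (
            msio.read_structure_table(inputs["structures"])
            if inputs.get("structures")
            else {}
        )
        transcripts = msio.attach_structures(
            msio.read_fasta(inputs["transcripts"]), structures
        )
        libraries = [
            msio.read_degradome(p) for p in sorted(inputs.get("degradome", []))
        ]
        truth = None

    results: dict = {"mirnas": mirnas, "transcripts": transcripts,
                     "libraries": libraries, "truth": truth}

    # --- mimic scan
    if "scan" in stages:
        scan_cfg = config["scan"]
        rules = MimicRuleParams(
            gu_counts_as_mismatch=scan_cfg.get("gu_counts_as_mismatch", True),
            max_middle_mismatches=scan_cfg.get("max_middle_mismatches"),
        )
        mimic_table = scan_transcriptome(mirnas, transcripts, ScanParams(rules=rules))
        path = os.path.join(out_dir, "mimics.tsv")
        msio.write_table(path, mimic_table)
        record("scan", path)
        results["mimic_table"] = mimic_table

    # --- region annotation and distribution statistics
    if "annotate" in stages and "mimic_table" in results:
        unique = ann.dedup_sites(results["mimic_table"])
        annotated = ann.annotate_sites(unique, transcripts)
        summary = ann.distribution_summary(annotated, transcripts)
        persite = os.path.join(out_dir, "sites_annotated.tsv")
        summ = os.path.join(out_dir, "distribution_summary.tsv")
        tally = os.path.join(out_dir, "mimic_tally.tsv")
        msio.write_table(persite, annotated)
        msio.write_table(summ, summary.to_frame())
        msio.write_table(tally, ann.per_gene_tally(annotated, transcripts))
        record("annotate", persite, summ, tally)
        results["distribution"] = summary
        results["unique_sites"] = annotated

    # --- sequestered-miRNA sequence profiles
    if "profile" in stages and "mimic_table" in results:
        accepted = results["mimic_table"]
        accepted = accepted[accepted["accepted"]]
        sequestered_ids = sorted(set(accepted["mirna_id"]))
        results["sequestered_ids"] = sequestered_ids
        paths = []
        if sequestered_ids:
            seq_set, control = prof.split_sequestered(mirnas, sequestered_ids)
            comparisons = (
                prof.compare_sets(seq_set, control) if control
                else {"length": prof.length_histogram(seq_set).assign(set="sequestered"),
                      "terminal_5p": prof.terminal_composition(seq_set).assign(set="sequestered")}
            )
            for name, frame in comparisons.items():
                p = os.path.join(out_dir, f"profile_{name}.tsv")
                msio.write_table(p, frame)
                paths.append(p)
            for anchor in ("five_prime", "three_prime"):
                usable = [m for m in seq_set if len(m) >= prof.PROFILE_SPAN]
                if not usable:
                    continue
                profile = prof.positional_profile(usable, anchor)
                p = os.path.join(out_dir, f"profile_{anchor}.tsv")
                msio.write_table(p, profile.to_frame())
                paths.append(p)
        if paths:
            record("profile", *paths)

    # --- target prediction + degradome validation
    if "validate" in stages:
        val_cfg = config["validate"]
        score_params = val.TargetScoreParams(max_score=val_cfg.get("max_score", 3.0))
        vparams = val.ValidationParams(
            min_reads_same_5p=val_cfg.get("min_reads_same_5p", 3),
            prominence_fraction=val_cfg.get("prominence_fraction", 1.0),
            species_mode=val_cfg.get("species_mode", False),
        )
        query = [
            m for m in mirnas
            if not results.get("sequestered_ids") or m.id in results["sequestered_ids"]
        ]
        pairs = val.predict_all_targets(query, transcripts, score_params)
        pairs, signals = val.validate_pairs(pairs, libraries, transcripts, vparams)
        pair_table = val.pairs_to_frame(pairs)
        ppath = os.path.join(out_dir, "target_pairs.tsv")
        spath = os.path.join(out_dir, "cleavage_signals.tsv")
        msio.write_table(ppath, pair_table)
        msio.write_table(spath, signals)
        record("validate", ppath, spath)
        results["pair_table"] = pair_table

    # --- network construction and export
    if "network" in stages:
        g = net.build_network(
            results.get("mimic_table"), results.get("pair_table")
        )
        gml = os.path.join(out_dir, "network.graphml")
        sif = os.path.join(out_dir, "network.sif")
        stats_path = os.path.join(out_dir, "network_stats.json")
        net.export_network(g, gml, "graphml")
        net.export_network(g, sif, "sif")
        with open(stats_path, "w") as fh:
            json.dump(net.network_stats(g), fh, indent=2, sort_keys=True)
        record("network", gml, sif, sif + ".nodes.tsv", stats_path)
        results["network"] = g

    # --- truth scoring when running on simulated data
    if truth is not None and ("scan" in stages or "validate" in stages):
        scores = score_pipeline_against_truth(
            truth,
            mimic_table=results.get("mimic_table"),
            validated_pairs=results.get("pair_table"),
        )
        p = os.path.join(out_dir, "truth_scores.tsv")
        msio.write_table(p, scores)
        record("evaluate", p)
        results["truth_scores"] = scores

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
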