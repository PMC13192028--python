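"""End-to-end driver: counts -> variants -> clonotypes -> shifts -> CNV ->
trees -> concordance, with a JSON manifest of inputs, parameters and outputs.

Variant filter statistics are computed on cells pooled across each donor's
samples (matching how longitudinal samples are handled upstream); everything
downstream is per sample or per longitudinal pair.  All randomness derives
from the config seed, and outputs are byte-deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .clonotype import (
    call_clonotypes,
    clone_dynamics,
    downsample_stability,
    subclone_summary,
)
from .cnv import bin_fragments, cnv_deviation
from .config import RunConfig, SampleSheet
from .counts import BaseCountTensor
from .lineage import clone_concordance, nj_tree, repertoire_summary
from .shifts import combine_shift_results, ks_shift_test, mean_shift_screen
from .variants import (
    call_variants,
    calls_to_frame,
    compute_heteroplasmy,
    filter_variants,
    passing_ids,
)

logger = logging.getLogger(__name__)

ANALYSIS_COMPARTMENTS = ("monoclonal", "physiologic_b")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(sheet: SampleSheet, config: RunConfig, out_dir: str | Path,
                 base_dir: str | Path = ".") -> dict:
    """Run every applicable stage and return (and write) the manifest.

    CNV requires at least one sample with fragments *and* a ``t_reference``
    sample; an inconsistent sheet fails validation before any compute.
    """
    config.validate()
    base = Path(base_dir)
    sheet.validate(base)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cnv_targets = [
        s for s in sheet.samples
        if s.fragments is not None and s.compartment in ANALYSIS_COMPARTMENTS
    ]
    references = [s for s in sheet.samples if s.compartment == "t_reference"]
    if cnv_targets:
        if not references or all(r.fragments is None for r in references):
            raise ValueError(
                "CNV requested (fragments present) but sheet has no t_reference "
                "sample with fragments"
            )
        if sheet.chrom_sizes is None:
            raise ValueError("CNV requested but sheet has no chrom_sizes")

    manifest: dict = {"stages": [], "parameters": config.to_dict(), "outputs": []}
    inputs = {}
    for s in sheet.samples:
        for attr in ("counts", "fragments", "bcr"):
            path = getattr(s, attr)
            if path is not None:
                target = base / path
                if target.is_dir():
                    digest = hashlib.sha256(
                        b"".join(
                            _sha256(p).encode() for p in sorted(target.rglob("*")) if p.is_file()
                        )
                    ).hexdigest()
                else:
                    digest = _sha256(target)
                inputs[f"{s.id}:{attr}"] = digest
    manifest["inputs"] = inputs

    def _record(stage: str, outputs: list[str], **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        manifest["outputs"].extend(outputs)
        logger.info("stage %s done: %s", stage, info)

    try:
        # ------------------------------------------------------------ load
        tensors: dict[str, BaseCountTensor] = {}
        for s in sheet.samples:
            if s.counts is not None:
                tensors[s.id] = io.read_base_counts(base / s.counts)
        _record("load_counts", [], n_samples=len(tensors),
                n_cells={k: t.n_cells for k, t in tensors.items()})

        # ------------------------------------------------ variants per donor
        analysis_samples = [
            s for s in sheet.samples
            if s.id in tensors and s.compartment in ANALYSIS_COMPARTMENTS
        ]
        donors = sorted({s.donor for s in analysis_samples})
        donor_passing: dict[str, list[str]] = {}
        for donor in donors:
            donor_samples = [s for s in analysis_samples if s.donor == donor]
            pooled = BaseCountTensor.concat([tensors[s.id] for s in donor_samples])
            calls = call_variants(
                pooled,
                detection_threshold=config.detection_threshold,
                min_coverage=config.min_coverage,
            )
            compartment_means = None
            compartments = sorted({s.compartment for s in donor_samples})
            if len(compartments) > 1:
                vids = [c.variant_id for c in calls]
                compartment_means = {v: [] for v in vids}
                for comp in compartments:
                    comp_tensor = BaseCountTensor.concat(
                        [tensors[s.id] for s in donor_samples if s.compartment == comp]
                    )
                    het = compute_heteroplasmy(comp_tensor, vids, config.min_coverage)
                    for v in vids:
                        compartment_means[v].append(float(het[v].mean(skipna=True)))
            filtered = filter_variants(
                calls,
                blacklist=frozenset(config.blacklist),
                homoplasmy_cutoff=config.homoplasmy_cutoff,
                min_cells=config.min_cells,
                vmr_threshold=config.vmr_threshold,
                concordance_threshold=config.concordance_threshold,
                compartment_means=compartment_means,
            )
            donor_passing[donor] = passing_ids(filtered)
            table = calls_to_frame(filtered).sort_index()
            path = out / f"variants.{donor}.tsv"
            table.to_csv(path, sep="\t")
        _record(
            "call_variants",
            [f"variants.{d}.tsv" for d in donors],
            n_passing={d: len(v) for d, v in donor_passing.items()},
        )

        # -------------------------------------------------- heteroplasmy
        donor_of = {s.id: s.donor for s in analysis_samples}
        het_by_sample: dict[str, pd.DataFrame] = {}
        for s in analysis_samples:
            vids = donor_passing[donor_of[s.id]]
            het = compute_heteroplasmy(tensors[s.id], vids, config.min_coverage)
            het_by_sample[s.id] = het
            io.write_heteroplasmy(het, out / "heteroplasmy" / s.id)
        _record("heteroplasmy", [f"heteroplasmy/{s.id}" for s in analysis_samples])

        # -------------------------------------------------- clonotypes
        assignments = {}
        for s in analysis_samples:
            assign = call_clonotypes(
                het_by_sample[s.id],
                k=config.knn_k,
                resolution=config.resolution,
                min_marker_het=config.min_marker_het,
                merge_threshold=config.merge_threshold,
                seed=config.seed,
            )
            assignments[s.id] = assign
            io.write_clones(assign.labels, out / f"clones.{s.id}.tsv")
            assign.profiles.to_csv(out / f"clone_profiles.{s.id}.tsv", sep="\t")
        summary = subclone_summary(assignments)
        summary.to_csv(out / "subclone_summary.tsv", sep="\t", index=False)
        _record(
            "clonotype",
            [f"clones.{s.id}.tsv" for s in analysis_samples] + ["subclone_summary.tsv"],
            n_subclones={sid: a.n_clones for sid, a in assignments.items()},
        )

        # -------------------------------------------------- stability
        stability_rows = []
        for s in analysis_samples:
            report = downsample_stability(
                het_by_sample[s.id],
                fractions=tuple(config.stability_fractions),
                n_reps=config.stability_reps,
                threshold=config.stability_threshold,
                seed=config.seed,
                k=config.knn_k,
                resolution=config.resolution,
                min_marker_het=config.min_marker_het,
                merge_threshold=config.merge_threshold,
            )
            medians = report.median_agreement()
            stable = report.stable()
            for fraction in medians.index:
                stability_rows.append(
                    {
                        "sample": s.id,
                        "fraction": fraction,
                        "median_agreement": medians[fraction],
                        "stable": bool(stable[fraction]),
                    }
                )
        pd.DataFrame(stability_rows).to_csv(out / "stability.tsv", sep="\t", index=False)
        _record("stability", ["stability.tsv"])

        # -------------------- longitudinal pairs: shift screens + dynamics
        pair_outputs = []
        monoclonal = [s for s in analysis_samples if s.compartment == "monoclonal"]
        for donor in donors:
            serial = [s for s in monoclonal if s.donor == donor]
            if len(serial) < 2:
                continue
            a, b = serial[0], serial[1]
            mean_screen = mean_shift_screen(
                het_by_sample[a.id], het_by_sample[b.id],
                fc_threshold=config.fc_threshold, alpha=config.alpha,
            )
            ks_screen = ks_shift_test(
                het_by_sample[a.id], het_by_sample[b.id],
                min_cells=config.ks_min_cells, alpha=config.alpha,
                gate=config.ks_gate,
            )
            combined = combine_shift_results(mean_screen, ks_screen)
            combined.to_csv(out / f"shift_results.{donor}.tsv", sep="\t")
            dynamics = clone_dynamics(
                assignments[a.id], assignments[b.id],
                min_cells=config.dynamics_min_cells,
                fc_threshold=config.fc_threshold, alpha=config.alpha,
            )
            dynamics.to_csv(out / f"dynamics.{donor}.tsv", sep="\t", index=False)
            pair_outputs += [f"shift_results.{donor}.tsv", f"dynamics.{donor}.tsv"]
        _record("shift_tests", pair_outputs, n_pairs=len(pair_outputs) // 2)

        # -------------------------------------------------- CNV
        cnv_outputs = []
        if cnv_targets:
            chrom_sizes = io.read_chrom_sizes(base / sheet.chrom_sizes)
            ref_frags = pd.concat(
                [io.read_fragments(base / r.fragments) for r in references if r.fragments],
                ignore_index=True,
            )
            ref_barcodes = sorted(ref_frags["barcode"].unique())
            reference_bins = bin_fragments(
                ref_frags, ref_barcodes, chrom_sizes,
                bin_size=config.bin_size, step=config.step,
            )
            for s in cnv_targets:
                frags = io.read_fragments(base / s.fragments)
                barcodes = sorted(frags["barcode"].unique())
                target_bins = bin_fragments(
                    frags, barcodes, chrom_sizes,
                    bin_size=config.bin_size, step=config.step,
                )
                profile = cnv_deviation(
                    target_bins, reference_bins,
                    min_ref_cells=config.min_ref_cells,
                    min_bins=config.min_bins, z_threshold=config.z_threshold,
                )
                profile.to_frame().to_csv(out / f"cnv_zscores.{s.id}.tsv", sep="\t", index=False)
                profile.segments.to_csv(out / f"cnv_segments.{s.id}.bed", sep="\t", index=False)
                cnv_outputs += [f"cnv_zscores.{s.id}.tsv", f"cnv_segments.{s.id}.bed"]
        _record("cnv", cnv_outputs, n_targets=len(cnv_targets))

        # -------------------------------------------------- trees
        tree_outputs = []
        for s in analysis_samples:
            profiles = assignments[s.id].profiles
            profiles = profiles.loc[[c for c in profiles.index if c != 0]]
            if len(profiles) < 2:
                continue
            tree = nj_tree(profiles, max_leaves=config.tree_max_leaves, seed=config.seed)
            io.write_newick(tree.newick, out / f"tree.{s.id}.nwk")
            tree_outputs.append(f"tree.{s.id}.nwk")
        _record("trees", tree_outputs)

        # -------------------------------------------------- BCR concordance
        concordance_outputs = []
        for s in analysis_samples:
            if s.bcr is None:
                continue
            repertoire = io.read_airr(base / s.bcr)
            summary = repertoire_summary(repertoire)
            io.write_json(summary, out / f"repertoire.{s.id}.json")
            bcr_labels = pd.Series(
                repertoire["clone_id"].to_numpy(),
                index=pd.Index(repertoire["cell_id"], name="cell"),
            )
            result = clone_concordance(assignments[s.id].labels, bcr_labels)
            result.flows.to_csv(out / f"concordance.{s.id}.tsv", sep="\t", index=False)
            io.write_json(
                {"ari": result.ari, "n_cells": result.n_cells},
                out / f"concordance.{s.id}.json",
            )
            concordance_outputs += [
                f"repertoire.{s.id}.json",
                f"concordance.{s.id}.tsv",
                f"concordance.{s.id}.json",
            ]
        _record("concordance", concordance_outputs)
    except Exception:
        io.write_json(manifest, out / "manifest.partial.json")
        raise

    io.write_json(manifest, out / "manifest.json")
    return manifest
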