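"""End-to-end orchestration: load → normalize → assign → profile →
stratify → stats, with a run report of counts at every stage.

All outputs are plain TSV/JSON under one directory with fixed names, so
reruns are diffable; figures are optional artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assign, metagene, normalize, stats, stratify
from .assign import BinScheme
from .genome_model import GenomeAnnotation, read_annotation, read_probe_layout

logger = logging.getLogger(__name__)

TRACK_EXPERIMENTS = {
    "polII": ("polII_ip", "input"),
    "h3": ("h3_ip", "input"),
    "k36_raw": ("k36_ip", "input"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    annotation: Path
    genome: Path
    probes: Path
    signal_manifest: Path
    expression: Path
    out_dir: Path
    scheme: BinScheme = field(default_factory=BinScheme)
    n_groups: int = 10
    log_level: str = "INFO"
    make_figures: bool = False

    @classmethod
    def from_bundle(cls, bundle_dir, out_dir, **kw) -> "RunConfig":
        """Point every input at a fixture-bundle directory (manifest.yaml)."""
        b = Path(bundle_dir)
        with open(b / "manifest.yaml") as fh:
            m = yaml.safe_load(fh)
        return cls(
            annotation=b / m["annotation"], genome=b / m["genome"],
            probes=b / m["probes"], signal_manifest=b / "manifest.yaml",
            expression=b / m["expression"], out_dir=Path(out_dir), **kw,
        )


def _load_signals(manifest_path: Path) -> dict[str, list[normalize.SignalArray]]:
    base = manifest_path.parent
    with open(manifest_path) as fh:
        m = yaml.safe_load(fh)
    arrays: dict[str, list[normalize.SignalArray]] = {}
    for exp, entries in m["signals"].items():
        arrays[exp] = [
            normalize.read_signal_tsv(base / e["path"], exp, e["replicate_id"])
            for e in entries
        ]
    return arrays


def validate_inputs(config: RunConfig) -> dict:
    """Consistency checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    for name in ("annotation", "genome", "probes", "signal_manifest", "expression"):
        p = getattr(config, name)
        if not Path(p).exists():
            errors.append(f"missing input file for role {name!r}: {p}")
    if errors:
        return {"errors": errors, "warnings": warnings_}

    ann = read_annotation(config.annotation)
    probes = read_probe_layout(config.probes)
    arrays = _load_signals(config.signal_manifest)
    for exp in ("polII_ip", "input", "h3_ip", "k36_ip", "faire", "gdna"):
        if not arrays.get(exp):
            errors.append(f"signal manifest has no arrays for role {exp!r}")
    ref = None
    for exp, reps in arrays.items():
        for arr in reps:
            if ref is None:
                ref = arr.values.index
            elif not ref.equals(arr.values.index):
                diff = len(ref.symmetric_difference(arr.values.index))
                errors.append(
                    f"{exp}/{arr.replicate_id}: probe set differs from the "
                    f"first array ({diff} probes in the symmetric difference)"
                )
    if ref is not None:
        layout_ids = pd.Index([p.probe_id for p in probes])
        missing = len(layout_ids.difference(ref))
        if missing:
            errors.append(f"{missing} layout probe(s) missing from signal arrays")
    probe_chroms = {p.chrom for p in probes}
    unknown = probe_chroms - set(ann.chrom_lengths)
    if unknown:
        errors.append(f"probe chromosomes absent from annotation: {sorted(unknown)}")
    expr = stratify.read_expression_tsv(config.expression)
    n_unknown = int((~expr["gene_id"].isin(ann.genes.keys())).sum())
    if n_unknown:
        warnings_.append(f"{n_unknown} expression gene(s) absent from annotation (dropped)")
    return {"errors": errors, "warnings": warnings_}


def build_tracks(arrays: dict[str, list[normalize.SignalArray]]
                 ) -> dict[str, normalize.EnrichmentTrack]:
    """All normalized enrichment tracks from the raw arrays."""
    tracks: dict[str, normalize.EnrichmentTrack] = {}
    for name, (ip, ctrl) in TRACK_EXPERIMENTS.items():
        tracks[name] = normalize.subtract_input(arrays[ip], arrays[ctrl], name=name)
    tracks["k36_norm"] = normalize.normalize_k36_by_h3(tracks["k36_raw"], tracks["h3"])
    tracks["faire"] = normalize.normalize_faire(arrays["faire"], arrays["gdna"])
    return tracks


PROFILE_TRACKS = ("polII", "h3", "k36_norm", "faire")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write TSV/JSON outputs; returns the report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "status": "running"}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                report["status"] = f"failed at {name}"
                with open(out / "report.json", "w") as fh:
                    json.dump(report, fh, indent=1, default=str)
                raise PipelineError(name, exc) from exc
        return deco

    @stage("load")
    def loaded():
        ann = read_annotation(config.annotation)
        probes = read_probe_layout(config.probes)
        arrays = _load_signals(config.signal_manifest)
        expr = stratify.read_expression_tsv(config.expression)
        import pyfaidx
        genome = pyfaidx.Fasta(str(config.genome))
        return ann, probes, arrays, expr, genome

    ann, probes, arrays, expr, genome = loaded
    report["stages"]["load"] = {
        "n_genes": len(ann), "n_spliced": len(ann.spliced_genes()),
        "n_unspliced": len(ann.unspliced_genes()), "n_probes": len(probes),
        "n_arrays": sum(len(v) for v in arrays.values()),
    }

    @stage("normalize")
    def tracks():
        return build_tracks(arrays)

    report["stages"]["normalize"] = {
        name: int(len(t.values)) for name, t in tracks.items()
    }

    @stage("assign")
    def tables():
        return assign.assign_probes(ann, probes, config.scheme)

    n_probes = len(probes)
    n_class = tables.classes["klass"].value_counts().to_dict()
    n_binned = tables.bins["probe_id"].nunique()
    report["stages"]["assign"] = {
        "n_probes": n_probes,
        "n_probes_in_bins": int(n_binned),
        "n_probes_outside": int(len(tables.outside_probe_ids)),
        "classes": {k: int(v) for k, v in n_class.items()},
    }
    assign.write_assignment_tsv(tables, out / "assignments.tsv")

    @stage("profile")
    def profiles():
        spliced_bins = tables.bins[tables.bins["spliced"]]
        unspliced_bins = tables.bins[~tables.bins["spliced"]]
        out_p = []
        for tname in PROFILE_TRACKS:
            out_p.append(metagene.profile_from_bins(
                spliced_bins, tracks[tname], metagene.LAYOUT_SPLICED, "all"))
            out_p.append(metagene.profile_from_bins(
                unspliced_bins, tracks[tname], metagene.LAYOUT_UNSPLICED, "all"))
        return out_p

    metagene.write_profile_tsv(profiles, out / "profiles.tsv")
    report["stages"]["profile"] = {"n_profiles": len(profiles)}

    @stage("background")
    def background():
        return metagene.estimate_background(tracks["polII"], tables)

    report["stages"]["background"] = dataclasses.asdict(background)

    @stage("stratify")
    def bins_table():
        return stratify.filter_and_rank(expr, ann, n_groups=config.n_groups)

    report["stages"]["stratify"] = bins_table.counts()
    stratify.write_decile_tsv(bins_table, out / "decile_table.tsv")

    @stage("decile_profiles")
    def decile_profiles():
        all_profiles = []
        for tname in PROFILE_TRACKS:
            by_layout = stratify.profiles_by_decile(
                bins_table, tracks[tname], ann, probes, config.scheme)
            for plist in by_layout.values():
                all_profiles.extend(plist)
        return all_profiles

    metagene.write_profile_tsv(decile_profiles, out / "decile_profiles.tsv")
    report["stages"]["decile_profiles"] = {"n_profiles": len(decile_profiles)}

    @stage("stats")
    def stat_report():
        rep: dict = {}
        for tname in PROFILE_TRACKS:
            bulk = stats.bulk_intron_exon_test(tracks[tname], tables.classes)
            rep[f"bulk_{tname}"] = {
                **bulk.welch.to_dict(), "exon_median": bulk.exon_median,
            }
        positions = stats.position_wise_tests(tracks["polII"], tables.classes, 3)
        rep["position_wise_polII"] = [
            {"ordinal": c.ordinal, **c.welch.to_dict(),
             "exon_quartiles": c.exon_quartiles, "intron_quartiles": c.intron_quartiles}
            for c in positions
        ]
        contrasts = stats.decile_contrasts(tracks["polII"], tables, bins_table, ann)
        rep["decile_contrasts_polII"] = [c.__dict__ for c in contrasts]
        stats.contrasts_to_frame(contrasts).to_csv(
            out / "decile_contrasts.tsv", sep="\t", index=False, float_format="%.6g")
        gc = stats.gc_boundary_test(ann.genes.values(), genome)
        rep["gc_boundary"] = gc.to_dict()
        return rep

    with open(out / "stats.json", "w") as fh:
        json.dump(stat_report, fh, indent=1, default=float)
    report["stages"]["stats"] = {"n_tests": len(stat_report)}

    if config.make_figures:
        _plot_profiles(profiles, out / "profiles.png")

    report["status"] = "success"
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _plot_profiles(profiles, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layouts = sorted({p.layout for p in profiles})
    fig, axes = plt.subplots(len(layouts), 1, figsize=(9, 3.2 * len(layouts)))
    if len(layouts) == 1:
        axes = [axes]
    for ax, layout in zip(axes, layouts):
        for p in [q for q in profiles if q.layout == layout]:
            ax.plot(range(len(p.bins)), p.bins["mean"], label=p.track_name)
        # vertical separators between regions
        segs = p.bins["segment"].to_numpy()
        for i in range(1, len(segs)):
            if segs[i] != segs[i - 1]:
                ax.axvline(i - 0.5, color="k", lw=0.5)
        ax.set_title(layout)
        ax.set_xlabel("bin")
        ax.set_ylabel("mean log2 enrichment")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
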