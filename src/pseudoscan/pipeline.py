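"""End-to-end orchestration: configuration, stages, reports, recovery scoring.

The pipeline ties the stages together: (optionally) simulate a truth-logged
dataset, map exons in every locus, classify lesions and verdicts, place
shared lesions and loss events on the species tree, and run the counting
selection screen.  Every output is a deterministic function of the config
plus seed; rerunning a config reproduces all TSVs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import dollo, selection, simulate, treeutil
from .gene_model import GeneModel, TargetLocus
from .integrity import GeneVerdict, evaluate_locus
from .mapping import NoGeneFoundError, ScoreParams, hits_to_tsv

STATUS_CODE = {"INTACT": "I", "INTACT_FUSION": "F", "PSEUDOGENE": "P", "INCOMPLETE": "U"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    out_dir: str
    model_path: Optional[str] = None
    loci_dir: Optional[str] = None
    tree_path: Optional[str] = None
    scenario_path: Optional[str] = None  # simulate stage input
    alignment_path: Optional[str] = None  # dnds stage input (codon FASTA)
    foreground: list[str] = field(default_factory=list)
    min_identity: float = 0.6
    rescue_window: int = 30
    offset_tolerance: int = 3
    alpha: float = 0.1
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["map", "classify", "events", "dnds"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_loci(loci_dir) -> list[TargetLocus]:
    from Bio import SeqIO

    loci = []
    for path in sorted(Path(loci_dir).glob("*.fasta")):
        sp = path.stem
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            continue
        loci.append(
            TargetLocus(species_id=sp, locus_id=recs[0].id, sequence=str(recs[0].seq).upper())
        )
    if not loci:
        raise ConfigError(f"no *.fasta loci in {loci_dir}")
    return loci


def evaluate_dataset(
    model: GeneModel,
    loci: Sequence[TargetLocus],
    params: ScoreParams = ScoreParams(),
    rescue_window: int = 30,
) -> dict[str, GeneVerdict]:
    """Classify every locus; species with no detectable gene get no verdict."""
    out: dict[str, GeneVerdict] = {}
    for locus in loci:
        try:
            out[locus.species_id] = evaluate_locus(
                model, locus, params=params, rescue_window=rescue_window
            )
        except NoGeneFoundError:
            continue
    return out


# ------------------------------------------------------------------ reports


def lesions_to_tsv(verdicts: Mapping[str, GeneVerdict]) -> str:
    """Lesion map: one row per lesion, 1-based offsets for human readers."""
    rows = [
        "species\tgene\texon\tkind\tboundary\toffset\tobserved\treference\tdisrupting\tsecondary\tnote"
    ]
    for sp in sorted(verdicts):
        v = verdicts[sp]
        for l in v.lesions:
            rows.append(
                "\t".join(
                    [
                        sp,
                        v.gene_id,
                        str(l.exon_number),
                        l.kind,
                        l.boundary or ".",
                        str(l.offset + 1) if l.offset is not None else ".",
                        l.observed or ".",
                        l.reference or ".",
                        "yes" if l.disrupting else "no",
                        "yes" if l.secondary else "no",
                        l.note or ".",
                    ]
                )
            )
    return "\n".join(rows) + "\n"


def fusions_to_tsv(verdicts: Mapping[str, GeneVerdict]) -> str:
    rows = ["species\tgene\tupstream_exon\tdownstream_exon\tintron_length\tincorporated_residues"]
    for sp in sorted(verdicts):
        v = verdicts[sp]
        for f in v.fusions:
            rows.append(
                f"{sp}\t{v.gene_id}\t{f.upstream_exon}\t{f.downstream_exon}\t"
                f"{f.intron_length}\t{f.incorporated_residues}"
            )
    return "\n".join(rows) + "\n"


def render_status_matrix(
    verdicts: Mapping[str, GeneVerdict] | Sequence[GeneVerdict],
    tree=None,
    genes: Optional[Sequence[str]] = None,
) -> str:
    """Species x gene status matrix (codes I/F/P/U) as TSV.

    Rows follow the tree's tip traversal when a tree is given, else sorted
    species order.  A (species, gene) pair without a verdict is reported U
    (no genomic information), never dropped.
    """
    if isinstance(verdicts, Mapping):
        vlist = list(verdicts.values())
    else:
        vlist = list(verdicts)
    if not vlist:
        raise ValueError("need at least one verdict")
    by_pair = {(v.species_id, v.gene_id): v for v in vlist}
    gene_ids = list(genes) if genes else sorted({v.gene_id for v in vlist})
    species = sorted({v.species_id for v in vlist})
    if tree is not None:
        t = treeutil.load_tree(tree)
        order = [lf for lf in treeutil.tip_labels(t)]
        species = [sp for sp in order if sp in set(species)] + [
            sp for sp in species if sp not in set(order)
        ]
    rows = ["species\t" + "\t".join(gene_ids)]
    for sp in species:
        cells = []
        for g in gene_ids:
            v = by_pair.get((sp, g))
            cells.append(STATUS_CODE[v.status] if v else "U")
        rows.append(sp + "\t" + "\t".join(cells))
    return "\n".join(rows) + "\n"


def render_status_figure(matrix_tsv: str, path) -> None:
    """Optional heat-map figure of the status matrix (blue/turquoise/magenta/grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    lines = [l.split("\t") for l in matrix_tsv.strip().splitlines()]
    genes = lines[0][1:]
    species = [r[0] for r in lines[1:]]
    codes = {"I": 0, "F": 1, "P": 2, "U": 3}
    data = [[codes[c] for c in r[1:]] for r in lines[1:]]
    cmap = ListedColormap(["#3b6fb5", "#31c5c5", "#d43f8d", "#b0b0b0"])
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(genes), 0.9 + 0.3 * len(species)))
    ax.imshow(data, cmap=cmap, vmin=0, vmax=3, aspect="auto")
    ax.set_xticks(range(len(genes)), genes)
    ax.set_yticks(range(len(species)), species)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -------------------------------------------------------- recovery scoring


def _expected_predictions(ev: simulate.PlantedEvent) -> set[tuple[str, int]]:
    k = ev.exon_number
    if ev.kind == simulate.EXON_DELETION:
        return {("EXON_MISSING", k)}
    if ev.kind == simulate.EXON_FUSION:
        # a fusion presents as the fusion call plus the mutated-donor record
        return {("FUSION", k), ("SPLICE_DONOR_MUT", k)}
    return {(ev.kind, k)}


def _required_prediction(ev: simulate.PlantedEvent) -> tuple[str, int]:
    if ev.kind == simulate.EXON_DELETION:
        return ("EXON_MISSING", ev.exon_number)
    if ev.kind == simulate.EXON_FUSION:
        return ("FUSION", ev.exon_number)
    return (ev.kind, ev.exon_number)


def score_recovery(
    truth: simulate.SimTruth, verdicts: Mapping[str, GeneVerdict]
) -> dict:
    """Lesion-level sensitivity/precision and verdict accuracy against SimTruth.

    Predictions are the primary lesions plus fusion calls of each verdict
    (secondary premature STOPs are consequences of frame changes, not
    independent mutations, and are excluded on both sides of the match).
    """
    tp = fn = fp = 0
    verdict_ok = verdict_total = 0
    for sp, tip in truth.tips.items():
        v = verdicts.get(sp)
        predicted: set[tuple[str, int]] = set()
        if v is not None:
            for l in v.primary_lesions:
                predicted.add((l.kind, l.exon_number))
            for f in v.fusions:
                predicted.add(("FUSION", f.upstream_exon))
        explained: set[tuple[str, int]] = set()
        for ev in tip.events:
            req = _required_prediction(ev)
            if req in predicted:
                tp += 1
            else:
                fn += 1
            explained |= _expected_predictions(ev)
        fp += len(predicted - explained)
        verdict_total += 1
        if v is not None and v.status == tip.status:
            verdict_ok += 1
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    prec = tp / (tp + fp) if (tp + fp) else 1.0
    return {
        "true_positives": tp,
        "false_negatives": fn,
        "false_positives": fp,
        "sensitivity": sens,
        "precision": prec,
        "verdict_accuracy": verdict_ok / verdict_total if verdict_total else 1.0,
        "n_loci": verdict_total,
    }


# ------------------------------------------------------------------ pipeline


@dataclass
class RunResult:
    exit_code: int
    outputs: dict[str, list[str]]
    summary: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the configured stages; write TSV/JSON reports plus a MANIFEST.

    Returns exit code 0 on success, 1 on a stage failure (partial outputs
    retained, MANIFEST marks completeness); raises :class:`ConfigError`
    (exit code 2 at the CLI) on bad input before any computation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    for p, what in (
        (config.model_path, "model_path"),
        (config.tree_path, "tree_path"),
        (config.loci_dir, "loci_dir"),
        (config.scenario_path, "scenario_path"),
        (config.alignment_path, "alignment_path"),
    ):
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{what} does not exist: {p}")
    if "simulate" not in stages and any(s in stages for s in ("map", "classify", "events")):
        if config.scenario_path is None and (config.model_path is None or config.loci_dir is None):
            raise ConfigError("map/classify stages need model_path + loci_dir (or a scenario)")

    outputs: dict[str, list[str]] = {}
    # provenance config: path fields reduced to basenames so that two runs of
    # the same inputs from different directories stay byte-identical
    prov = config.to_dict()
    prov["out_dir"] = "."  # the record lives inside the output directory
    for key in ("model_path", "loci_dir", "tree_path", "scenario_path", "alignment_path"):
        if prov.get(key):
            prov[key] = Path(prov[key]).name
    summary: dict = {"config": prov, "stages": {}}
    log = lambda msg: print(msg, file=sys.stderr)  # noqa: E731

    model: Optional[GeneModel] = None
    loci: Optional[list[TargetLocus]] = None
    tree_src = config.tree_path
    truth = None
    verdicts: dict[str, GeneVerdict] = {}

    def _write(name: str, text: str, stage: str):
        path = out / name
        path.write_text(text)
        outputs.setdefault(stage, []).append(name)

    exit_code = 0
    try:
        if "simulate" in stages or config.scenario_path is not None:
            if config.scenario_path is not None:
                with open(config.scenario_path) as fh:
                    scen = simulate.Scenario.from_dict(
                        yaml.safe_load(fh)
                        if str(config.scenario_path).endswith((".yaml", ".yml"))
                        else json.load(fh)
                    )
            else:
                raise ConfigError("simulate stage needs scenario_path")
            log(f"[simulate] scenario seed={scen.seed} tips in {scen.tree_newick[:40]}...")
            model, loci, truth = simulate.run_scenario(scen)
            sim_dir = out / "sim"
            simulate.write_fixture(loci, truth, sim_dir, config=scen.to_dict())
            (sim_dir / "model.json").write_text(model.to_json())
            outputs["simulate"] = [f"sim/{p.name}" for p in sorted(sim_dir.iterdir())]
            summary["stages"]["simulate"] = {"n_loci": len(loci), "n_events": len(scen.planted)}
            tree_src = tree_src or scen.tree_newick

        if model is None and config.model_path:
            model = GeneModel.from_json(Path(config.model_path).read_text())
        if loci is None and config.loci_dir:
            loci = read_loci(config.loci_dir)

        params = ScoreParams(min_identity=config.min_identity)

        if "map" in stages or "classify" in stages or "events" in stages:
            if model is None or loci is None:
                raise ConfigError("map stage needs a model and loci")
            log(f"[map/classify] {len(loci)} loci x {len(model.exons)} exons")
            verdicts = evaluate_dataset(
                model, loci, params=params, rescue_window=config.rescue_window
            )
            map_rows = []
            for sp in sorted(verdicts):
                v = verdicts[sp]
                locus = next(l for l in loci if l.species_id == sp)
                map_rows.append(hits_to_tsv(v.hits, locus))
            header, *rest = map_rows[0].splitlines()
            body = [header] + [
                line
                for block in map_rows
                for line in block.splitlines()[1:]
            ]
            _write("exon_hits.tsv", "\n".join(body) + "\n", "map")
            summary["stages"]["map"] = {"n_species": len(verdicts)}

        if "classify" in stages and verdicts:
            _write("verdicts.tsv", render_status_matrix(verdicts, tree=tree_src), "classify")
            _write("lesions.tsv", lesions_to_tsv(verdicts), "classify")
            _write("fusions.tsv", fusions_to_tsv(verdicts), "classify")
            statuses = {sp: v.status for sp, v in verdicts.items()}
            summary["stages"]["classify"] = {
                "statuses": dict(sorted(statuses.items())),
            }
            if truth is not None:
                summary["stages"]["classify"]["recovery"] = score_recovery(truth, verdicts)

        if "events" in stages and verdicts:
            if tree_src is None:
                raise ConfigError("events stage needs a tree")
            sigs = {
                sp: [
                    dollo.lesion_signature(l, v.gene_id, None)
                    for l in v.primary_lesions
                ]
                for sp, v in verdicts.items()
            }
            placements = dollo.map_events_on_tree(sigs, tree_src)
            _write("event_placements.tsv", dollo.placements_to_tsv(placements), "events")
            _write("events_annotated.nwk", dollo.annotated_newick(tree_src, placements), "events")
            statuses = {sp: v.status for sp, v in verdicts.items()}
            n_loss, stems = dollo.min_loss_events(statuses, tree_src)
            summary["stages"]["events"] = {
                "n_signatures": len(placements),
                "min_loss_events": n_loss,
                "loss_stems": stems,
            }

        if "dnds" in stages:
            aln = None
            if config.alignment_path:
                aln = selection.read_codon_alignment(config.alignment_path)
            elif verdicts:
                from .gene_model import STOP_CODONS

                cdss = {
                    sp: (
                        v.cds[:-3]
                        if v.cds[-3:] in STOP_CODONS  # drop the terminal STOP codon
                        else v.cds
                    )
                    for sp, v in verdicts.items()
                    if v.cds and v.status == "INTACT"
                }
                if len(cdss) >= 3 and len({len(s) for s in cdss.values()}) == 1:
                    aln = cdss
            if aln is None or tree_src is None:
                log("[dnds] skipped: no usable codon alignment and tree")
                summary["stages"]["dnds"] = {"skipped": True}
            else:
                tree = treeutil.load_tree(tree_src)
                keep = [sp for sp in treeutil.tip_labels(tree) if sp in aln]
                sub = tree.extract_tree_with_taxa(
                    taxa=[tree.taxon_namespace.get_taxon(sp) for sp in keep]
                )
                sub.is_rooted = True
                treeutil.label_nodes(sub)
                aln = {sp: aln[sp] for sp in keep}
                site = selection.site_selection_counts(aln, sub, alpha=config.alpha)
                rows = ["site\tsyn_changes\tnonsyn_changes\tp_value\tlabel\tmethod"]
                for ci in range(site.n_sites):
                    rows.append(
                        f"{ci + 1}\t{site.syn_changes[ci]:.3f}\t{site.nonsyn_changes[ci]:.3f}\t"
                        f"{site.p_values[ci]:.4g}\t{site.labels[ci]}\t{site.method}"
                    )
                _write("site_selection.tsv", "\n".join(rows) + "\n", "dnds")
                ref_sp = keep[0]
                rows = ["species_a\tspecies_b\tN\tS\tNd\tSd\tdN\tdS\tomega\tmethod"]
                for sp in keep[1:]:
                    r = selection.ng86_pairwise(aln[ref_sp], aln[sp])
                    omega = "NA" if r.omega is None else ("inf" if r.omega == float("inf") else f"{r.omega:.4f}")
                    rows.append(
                        f"{ref_sp}\t{sp}\t{r.N:.2f}\t{r.S:.2f}\t{r.Nd:.2f}\t{r.Sd:.2f}\t"
                        f"{r.dN:.4f}\t{r.dS:.4f}\t{omega}\t{r.method}"
                    )
                _write("pairwise_dnds.tsv", "\n".join(rows) + "\n", "dnds")
                summary["stages"]["dnds"] = {
                    "n_sites": site.n_sites,
                    "positive": site.n_positive,
                    "negative": site.n_negative,
                    "alpha": site.alpha,
                }
                if config.foreground:
                    fg = [sp for sp in config.foreground if sp in aln]
                    if len(fg) >= 1:
                        part = selection.clade_partition_dnds(aln, sub, fg)
                        summary["stages"]["dnds"]["omega_foreground"] = part.omega_foreground
                        summary["stages"]["dnds"]["omega_background"] = part.omega_background
    except ConfigError:
        raise
    except Exception as exc:  # stage failure: keep partial outputs
        log(f"[error] stage failure: {exc!r}")
        summary["error"] = repr(exc)
        exit_code = 1

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    manifest = {
        "complete": exit_code == 0,
        "stages": {s: sorted(fs) for s, fs in outputs.items()},
    }
    (out / "MANIFEST").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(exit_code=exit_code, outputs=outputs, summary=summary)
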