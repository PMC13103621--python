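"""End-to-end orchestration: simulate/ingest -> filter cascade -> analyses.

The pipeline mirrors a target-capture SNP workflow downstream of variant
calling.  Hard site filters and the dual-ploidy position intersection are
applied first; the surviving presence-filtered biallelic panel then feeds
three branches:

* ``coancestry`` — least-missing top-N panel -> Ritland matrix + heatmap order;
* ``phylip``     — singleton/missingness screen -> pruned PHYLIP alignment;
* ``structure``  — distance thinning -> structure genotype file;
* ``inheritance``— per-group allele/genotype spectra and mode verdicts.

Every run writes a JSON manifest with stage survivor counts, the full
parameter set, and sha256 checksums of all outputs; identical config and
seed give identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filtering, vcfio
from .coancestry import coancestry_matrix, order_for_heatmap
from .containers import GenotypeMatrix
from .exporters import export_phylip, export_structure, export_structure_params
from .inheritance import (
    InsufficientDataError,
    classify_inheritance,
    genotype_spectrum,
    plot_spectrum,
)
from .simulate import (
    InfoFieldModel,
    PopulationSpec,
    SimulationConfig,
    simulate_genotypes,
)


@dataclass
class FilterParams:
    min_qd: float = 2.0
    max_fs: float = 60.0
    min_mq: float = 40.0
    min_presence: float = 0.80
    max_missing: float = 0.20
    min_gap_bp: int = 10_000
    n_least_missing: int = 50_000


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int
    simulate: SimulationConfig | None = None
    diploid_vcf: str | None = None
    tetraploid_vcf: str | None = None
    sample_sheet: str | None = None
    filters: FilterParams = field(default_factory=FilterParams)
    analyses: list[str] = field(
        default_factory=lambda: ["coancestry", "inheritance", "phylip", "structure"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if "simulate" in raw:
            s = dict(raw["simulate"])
            pops = [PopulationSpec(**p) for p in s.pop("populations")]
            info = InfoFieldModel(**s.pop("info", {}))
            peds = [tuple(p) for p in s.pop("pedigree_pairs", [])]
            sim = SimulationConfig(
                populations=pops,
                info=info,
                pedigree_pairs=peds,
                seed=s.pop("seed", raw["seed"]),
                **s,
            )
        inputs = raw.get("inputs", {})
        return cls(
            output_dir=raw["output_dir"],
            seed=raw["seed"],
            simulate=sim,
            diploid_vcf=inputs.get("diploid_vcf"),
            tetraploid_vcf=inputs.get("tetraploid_vcf"),
            sample_sheet=inputs.get("sample_sheet"),
            filters=FilterParams(**raw.get("filters", {})),
            analyses=raw.get(
                "analyses", ["coancestry", "inheritance", "phylip", "structure"]
            ),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline; returns the run directory.

    Fails before any stage runs if a configured input path does not
    resolve; any stage failure aborts with the stage named, leaving the
    partial manifest on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    manifest["filters"] = asdict(config.filters)
    manifest_path = out / "manifest.json"

    def _save_manifest() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # ---- pre-flight ----
    for label in ("diploid_vcf", "tetraploid_vcf", "sample_sheet"):
        p = getattr(config, label)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured {label} not found: {p}")
    if config.simulate is None and (
        config.diploid_vcf is None or config.tetraploid_vcf is None
    ):
        raise ValueError("need either a simulate section or both input VCFs")

    stage = "simulate"
    try:
        # ---- inputs ----
        if config.simulate is not None:
            truth = simulate_genotypes(config.simulate)
            tet_path = out / "tetraploid_called.vcf"
            dip_path = out / "diploid_called.vcf"
            sheet_path = out / "samples.tsv"
            vcfio.write_vcf(truth, tet_path)
            vcfio.write_vcf(truth, dip_path, diploid_called=True)
            vcfio.write_sample_sheet(truth, sheet_path)
            manifest["stages"]["simulate"] = {
                "n_samples": truth.n_samples,
                "n_sites": truth.n_sites,
            }
        else:
            tet_path = Path(config.tetraploid_vcf)
            dip_path = Path(config.diploid_vcf)
            sheet_path = Path(config.sample_sheet) if config.sample_sheet else None

        stage = "read_vcf"
        sheet = vcfio.read_sample_sheet(sheet_path) if sheet_path else None
        tet = vcfio.read_vcf(tet_path, sheet)
        dip = vcfio.read_vcf(dip_path, sheet, check_ploidy=False)
        if sheet is not None:
            # genotype payload ploidy comes from the sheet, not the rendering
            ploidy = sheet.set_index("sample_id")["ploidy"]
            tet.ploidy = np.array([int(ploidy[s]) for s in tet.samples])

        stage = "hard_filter"
        f = config.filters
        report = filtering.FilterReport()
        dipf, _ = filtering.hard_filter(
            dip, min_qd=f.min_qd, max_fs=f.max_fs, min_mq=f.min_mq
        )
        tetf, report = filtering.hard_filter(
            tet, min_qd=f.min_qd, max_fs=f.max_fs, min_mq=f.min_mq, report=report
        )

        stage = "intersect"
        merged, report = filtering.intersect_ploidy_callsets(dipf, tetf, report=report)

        stage = "presence_biallelic"
        panel, report = filtering.presence_biallelic_filter(
            merged, min_presence=f.min_presence, report=report
        )

        for name, n_in, n_rm, n_out in report.stages:
            manifest["stages"][name] = {"in": n_in, "removed": n_rm, "out": n_out}
        report.to_tsv(out / "filter_report.tsv")

        # ---- branches ----
        if "coancestry" in config.analyses:
            stage = "coancestry"
            top, _ = filtering.select_least_missing(panel, n=f.n_least_missing)
            cm = coancestry_matrix(top)
            cm.to_tsv(out / "coancestry.tsv", out / "coancestry_loci.tsv")
            order = order_for_heatmap(cm)
            (out / "heatmap_order.txt").write_text(
                "\n".join(cm.sample_ids[i] for i in order) + "\n"
            )
            manifest["stages"]["coancestry"] = {"n_loci": top.n_sites}

        if "inheritance" in config.analyses:
            stage = "inheritance"
            rows = []
            groups = sorted(set(panel.groups.values()))
            for g in groups:
                members = [s for s in panel.samples if panel.groups.get(s) == g]
                try:
                    spec = genotype_spectrum(panel, members, group=g)
                    verdict, fits = classify_inheritance(spec)
                except (InsufficientDataError, ValueError) as exc:
                    rows.append({"group": g, "verdict": f"insufficient data ({exc})"})
                    continue
                for fit in fits:
                    rows.append(
                        {
                            "group": g,
                            "verdict": verdict,
                            "model": fit.model,
                            "rmse": fit.rmse,
                            "five_class_score": fit.five_class_score,
                            "n_sites": fit.n_sites,
                        }
                    )
                plot_spectrum(spec, fits, out / f"spectrum_{g}.png")
            pd.DataFrame(rows).to_csv(out / "inheritance.tsv", sep="\t", index=False)

        if "phylip" in config.analyses:
            stage = "phylip"
            phy_panel, _ = filtering.singleton_missingness_filter(
                panel, max_missing=f.max_missing
            )
            n, m = export_phylip(phy_panel, out / "alignment.phy")
            manifest["stages"]["phylip"] = {"n_samples": n, "n_sites": m}

        if "structure" in config.analyses:
            stage = "structure"
            thinned, _ = filtering.thin_by_distance(panel, min_gap_bp=f.min_gap_bp)
            export_structure(thinned, out / "structure.str")
            export_structure_params(
                out / "mainparams",
                n_individuals=thinned.n_samples,
                n_loci=thinned.n_sites,
                ploidy=int(thinned.ploidy.max()),
            )
            manifest["stages"]["structure"] = {"n_sites": thinned.n_sites}

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _save_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    _save_manifest()
    return out
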