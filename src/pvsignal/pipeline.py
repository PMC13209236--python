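"""End-to-end pipeline: ingest or simulate, deduplicate, screen, stratify,
fit TTO and IME models, run MR, and write result tables with a run manifest.

Every stage writes a CSV whose first line is a schema-version comment; the
manifest records the config hash, seeds, per-stage row counts and drop
tallies, so a run is fully auditable and reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import faers, ime, mr, signals, tto
from .errors import PvSignalError, SampleSizeError, FitError, MRInputError
from .simulate import FaersSimConfig, GwasSimConfig, generate_faers, generate_gwas
from .simulate.faers_sim import DemographicsSpec, DrugSpec, ImeLogitSpec

SCHEMA_VERSION = 1

#: Table-4 default thresholds; any override is flagged in the manifest
DEFAULT_THRESHOLDS = {"min_a": 3, "gender_min_count": 3}

ALL_STAGES = ("simulate", "dedup", "screen", "gender", "tto", "ime", "mr")


class PipelineStageError(PvSignalError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    mode: str = "synthetic"                    # synthetic | files
    seed: int = 0
    out_dir: str = "results"
    drugs: list = dataclasses.field(default_factory=lambda: [
        "vorinostat", "romidepsin", "belinostat", "panobinostat"])
    thresholds: dict = dataclasses.field(default_factory=dict)
    tto_offset_days: int = 1
    paths: dict = dataclasses.field(default_factory=dict)
    synthetic: dict = dataclasses.field(default_factory=dict)
    gwas: dict = dataclasses.field(default_factory=lambda: {"enabled": True})
    raw: dict = dataclasses.field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)} - {"raw"}
        unknown = set(data) - known - {"schema"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in data.items() if k in known}
        cfg = cls(**kwargs, raw=dict(data))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be synthetic or files, got {self.mode!r}")
        if not self.drugs:
            raise ValueError("config must name at least one query drug")
        if self.mode == "files":
            needed = {"demo", "drug", "reac", "ther", "outc", "meddra"}
            missing = sorted(needed - set(self.paths))
            if missing:
                raise ValueError(f"files mode needs paths for: {missing}")
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")

    def threshold(self, key: str):
        return self.thresholds.get(key, DEFAULT_THRESHOLDS[key])

    def threshold_overrides(self) -> dict:
        return {k: v for k, v in self.thresholds.items()
                if v != DEFAULT_THRESHOLDS[k]}

    def config_hash(self) -> str:
        blob = json.dumps(self.raw or dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _faers_sim_config(cfg: RunConfig) -> FaersSimConfig:
    params = dict(cfg.synthetic)
    if "drugs" in params:
        params["drugs"] = [DrugSpec(**d) for d in params["drugs"]]
    if "demographics" in params:
        params["demographics"] = DemographicsSpec(**params["demographics"])
    if "ime_logit" in params:
        params["ime_logit"] = ImeLogitSpec(**params["ime_logit"])
    params.setdefault("seed", cfg.seed)
    return FaersSimConfig(**params)


def _gwas_sim_config(cfg: RunConfig) -> tuple[GwasSimConfig, mr.GeneLocus]:
    params = {k: v for k, v in cfg.gwas.items() if k not in ("enabled", "gene")}
    gene = cfg.gwas.get("gene", {"symbol": "HDAC5", "chrom": "1",
                                 "start": 1_000_000, "end": 1_100_000})
    locus = mr.GeneLocus(gene=gene["symbol"], chrom=str(gene["chrom"]),
                         start=int(gene["start"]), end=int(gene["end"]))
    params.setdefault("seed", cfg.seed + 1)
    if "gene_window" not in params:
        params["gene_window"] = (locus.chrom, locus.start, locus.end)
    return GwasSimConfig(**params), locus


def write_csv(df: pd.DataFrame, path: Path, stage: str) -> None:
    """CSV with a schema-version header comment; 4 significant digits."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# pvsignal-schema={SCHEMA_VERSION} stage={stage}\n")
        df.to_csv(fh, index=False, float_format="%.4g", lineterminator="\n")


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the requested stages in order; returns results and manifest.

    Any stage failure raises :class:`PipelineStageError` naming the stage.
    """
    stages = set(ALL_STAGES if stages is None else stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "threshold_overrides": config.threshold_overrides(),
                "stages": {}}
    results: dict = {}

    # ---- ingest / simulate --------------------------------------------------
    stage = "simulate" if config.mode == "synthetic" else "ingest"
    try:
        if config.mode == "synthetic":
            sim_cfg = _faers_sim_config(config)
            tables, ledger = generate_faers(sim_cfg, outdir=out / "sim")
            meddra = faers.MeddraDict(sim_cfg.background_pts)
            results["truth_ledger"] = ledger
        else:
            tables = faers.read_faers_tables(
                {k: config.paths[k] for k in ("demo", "drug", "reac", "ther", "outc")})
            meddra = faers.MeddraDict.from_tsv(config.paths["meddra"])
        reports, warnings = faers.build_store(tables)
        manifest["stages"][stage] = {
            "rows_in": int(len(tables["demo"])), "rows_out": len(reports),
            "dropped": int(len(tables["demo"])) - len(reports),
            "warnings": dict(warnings)}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if not stages - {"simulate"}:
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return {"manifest": manifest, **results}

    # ---- dedup ---------------------------------------------------------------
    try:
        store = faers.deduplicate(reports)
        manifest["stages"]["dedup"] = {
            "rows_in": len(reports), "rows_out": len(store),
            "dropped": len(reports) - len(store)}
        results["store"] = store
    except Exception as exc:
        raise PipelineStageError("dedup", exc) from exc

    per_drug_screen: dict[str, pd.DataFrame] = {}
    demo_frames, annual_frames, tto_rows, ime_frames, gender_frames = [], [], [], [], []

    for drug in config.drugs:
        try:
            subset = faers.select_primary_suspect(store, [drug])
        except Exception as exc:
            raise PipelineStageError("dedup", exc) from exc

        if "screen" in stages:
            try:
                if subset:
                    demo = faers.summarize_demographics(subset)
                    stats = {k: demo.attrs.get(k) for k in
                             ("n", "age_mean", "age_sd", "weight_mean", "weight_sd")}
                    demo.insert(0, "drug", drug)
                    demo_frames.append(demo)
                    manifest["stages"].setdefault("demographics", {})[drug] = stats
                ann = faers.annual_counts(subset)
                annual_frames.append(pd.DataFrame(
                    {"drug": drug, "year": list(ann), "count": list(ann.values())}))
                pt_screen = signals.screen_terms(
                    store, drug, level="PT", meddra=meddra,
                    min_a=config.threshold("min_a"))
                pt_screen.insert(0, "drug", drug)
                soc_screen = signals.screen_terms(
                    store, drug, level="SOC", meddra=meddra,
                    min_a=config.threshold("min_a"))
                soc_screen.insert(0, "drug", drug)
                per_drug_screen[drug] = pt_screen
                write_csv(pt_screen, out / f"screen_pt_{drug}.csv", "screen")
                write_csv(soc_screen, out / f"screen_soc_{drug}.csv", "screen")
                manifest["stages"].setdefault("screen", {})[drug] = {
                    "rows_in": len(store), "rows_out": int(len(pt_screen)),
                    "dropped": 0, "n_drug_reports": len(subset)}
            except Exception as exc:
                raise PipelineStageError("screen", exc) from exc

        if "gender" in stages:
            try:
                g = signals.gender_screen(store, drug,
                                          min_count=config.threshold("gender_min_count"))
                g.insert(0, "drug", drug)
                gender_frames.append(g)
            except Exception as exc:
                raise PipelineStageError("gender", exc) from exc

        if "tto" in stages:
            try:
                sample = tto.extract_tto(subset, drug,
                                         offset_days=config.tto_offset_days)
                entry = {"rows_in": len(subset), "rows_out": sample.n,
                         "dropped": sum(sample.exclusions.values()),
                         "exclusions": sample.exclusions}
                try:
                    fit = tto.fit_weibull(sample, drug=drug)
                    tto_rows.append(fit.to_row())
                except (SampleSizeError, FitError) as exc:
                    entry["skipped"] = str(exc)
                manifest["stages"].setdefault("tto", {})[drug] = entry
            except Exception as exc:
                raise PipelineStageError("tto", exc) from exc

        if "ime" in stages:
            try:
                table = ime.IMELogit(ime.ime_records(subset), drug=drug).fit("both")
                ime_frames.append(table)
                manifest["stages"].setdefault("ime", {})[drug] = {
                    "rows_in": len(subset), "rows_out": int(len(table)), "dropped": 0}
            except Exception as exc:
                raise PipelineStageError("ime", exc) from exc

    if "screen" in stages:
        if demo_frames:
            write_csv(pd.concat(demo_frames, ignore_index=True),
                      out / "demographics.csv", "demographics")
        if annual_frames:
            write_csv(pd.concat(annual_frames, ignore_index=True),
                      out / "annual_counts.csv", "annual")
        inter = signals.common_signals(per_drug_screen) if per_drug_screen else []
        write_csv(pd.DataFrame({"term": inter}), out / "common_signals.csv", "screen")
        results["screen"] = per_drug_screen
        results["common_signals"] = inter
    if "gender" in stages and gender_frames:
        gender_all = pd.concat(gender_frames, ignore_index=True)
        write_csv(gender_all, out / "gender_ror.csv", "gender")
        results["gender"] = gender_all
        manifest["stages"]["gender"] = {"rows_in": len(store),
                                        "rows_out": int(len(gender_all)),
                                        "dropped": 0}
    if "tto" in stages:
        tto_table = pd.DataFrame(tto_rows)
        write_csv(tto_table, out / "tto_weibull.csv", "tto")
        results["tto"] = tto_table
    if "ime" in stages and ime_frames:
        ime_all = pd.concat(ime_frames, ignore_index=True)
        write_csv(ime_all, out / "ime_logistic.csv", "ime")
        results["ime"] = ime_all

    # ---- MR ------------------------------------------------------------------
    if "mr" in stages and config.gwas.get("enabled", True):
        try:
            if config.mode == "synthetic":
                gwas_cfg, locus = _gwas_sim_config(config)
                exposure, outcome, ld, gwas_ledger = generate_gwas(
                    gwas_cfg, outdir=out / "sim_gwas")
                results["gwas_ledger"] = gwas_ledger
            else:
                exposure = pd.read_csv(config.paths["exposure"], sep="\t")
                outcome = pd.read_csv(config.paths["outcome"], sep="\t")
                ld = pd.read_csv(config.paths["ld"], sep="\t", index_col=0)
                _, locus = _gwas_sim_config(config)
            instruments = mr.select_instruments(exposure, locus, ld)
            pairs = mr.harmonize(instruments, outcome)
            model = mr.MRModel(pairs, gene=locus.gene,
                               outcome=config.gwas.get("outcome_name", "outcome"))
            mr_results = model.fit_all(seed=config.seed)
            summary = mr_results.summary()
            write_csv(summary, out / "mr_estimates.csv", "mr")
            write_csv(instruments.provenance, out / "mr_instruments.csv", "mr")
            results["mr"] = mr_results
            manifest["stages"]["mr"] = {
                "rows_in": int(len(exposure)),
                "rows_out": int(len(pairs)),
                "dropped": int(len(exposure)) - int(len(pairs)),
                "harmonization": pairs.attrs.get("counts", {})}
        except Exception as exc:
            raise PipelineStageError("mr", exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
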