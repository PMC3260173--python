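"""Pipeline orchestration, configuration and the command-line interface.

The pipeline mirrors the processing stages of a shotgun experiment:

    import -> (transpose PIS/NLS) -> build MasterScan -> run queries
           -> isotopic correction -> class normalization -> report

Configuration is one declarative TOML file; see :class:`ExperimentConfig`
for the key set.  Every stage logs its counts to stderr and any stage
error aborts with a stage-labeled message.
"""

from __future__ import annotations

import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import click

from . import quant, queries as builtin_queries, scanmodes, spectra_io, synthgen
from .chem_core import Tolerance
from .lipids import LIPID_CLASSES
from .masterscan import (
    MasterScan,
    MasterScanSettings,
    ResolutionModel,
    build_masterscan,
    load_masterscan,
    save_masterscan,
)
from .mfql import IdentificationRecord, QueryAst, parse_mfql, run_queries
from .spectra_io import Scan

logger = logging.getLogger("lipidquery")

__all__ = ["InputFile", "ExperimentConfig", "PipelineResult", "run_pipeline", "main"]


@dataclass
class InputFile:
    """One entry of the input manifest.

    ``mode`` is ``full`` (mzXML or peak list), ``pis`` (requires
    ``monitored``) or ``nls`` (requires ``delta``); ``format`` is sniffed
    from the extension (``.mzxml``/``.csv``/``.dta``) unless given.
    """

    path: Path
    sample_id: str
    mode: str = "full"
    format: Optional[str] = None
    ms_level: int = 1
    monitored: Optional[float] = None
    delta: Optional[float] = None
    precursor_mz: Optional[float] = None


@dataclass
class ExperimentConfig:
    """Declarative experiment description (normally read from TOML)."""

    inputs: List[InputFile] = field(default_factory=list)
    settings: MasterScanSettings = field(default_factory=MasterScanSettings)
    seed: int = 0
    results_path: Path = Path("results.csv")
    profiles_path: Optional[Path] = Path("profiles.csv")
    masterscan_path: Optional[Path] = Path("experiment.masterscan.json")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        base = path.parent

        res = doc.get("resolution", {})
        tol = doc.get("tolerances", {})
        thr = doc.get("thresholds", {})
        settings = MasterScanSettings(
            ms1_resolution=ResolutionModel(
                r0=float(res.get("ms1_r0", 7500.0)),
                slope=float(res.get("ms1_slope", 0.0)),
                m_ref=float(res.get("ms1_mref", 700.0)),
            ),
            ms2_resolution=ResolutionModel(
                r0=float(res.get("ms2_r0", 7500.0)),
                slope=float(res.get("ms2_slope", 0.0)),
                m_ref=float(res.get("ms2_mref", 700.0)),
            ),
            ms1_tolerance=Tolerance(
                float(tol.get("ms1", 10.0)), tol.get("ms1_unit", "ppm")
            ),
            ms2_tolerance=Tolerance(
                float(tol.get("ms2", 15.0)), tol.get("ms2_unit", "ppm")
            ),
            virtual_fragment_tolerance=Tolerance(
                float(tol.get("virtual_fragment", 0.1)),
                tol.get("virtual_fragment_unit", "da"),
            ),
            precursor_window=float(tol.get("precursor_window", 0.5)),
            min_intensity=float(thr.get("min_intensity", 0.0)),
            min_occupancy=float(thr.get("min_occupancy", 0.0)),
            occupancy_unit=thr.get("occupancy_unit", "samples"),
        )
        out = doc.get("output", {})
        inputs = []
        for entry in doc.get("inputs", []):
            inputs.append(
                InputFile(
                    path=(base / entry["path"]).resolve(),
                    sample_id=entry["sample_id"],
                    mode=entry.get("mode", "full"),
                    format=entry.get("format"),
                    ms_level=int(entry.get("ms_level", 1)),
                    monitored=entry.get("monitored"),
                    delta=entry.get("delta"),
                    precursor_mz=entry.get("precursor_mz"),
                )
            )
        return cls(
            inputs=inputs,
            settings=settings,
            seed=int(doc.get("seed", 0)),
            results_path=base / out.get("results", "results.csv"),
            profiles_path=(base / p) if (p := out.get("profiles", "profiles.csv")) else None,
            masterscan_path=(base / p)
            if (p := out.get("masterscan", "experiment.masterscan.json"))
            else None,
        )


@dataclass
class PipelineResult:
    masterscan: MasterScan
    records: List[IdentificationRecord]
    profiles: List[quant.ClassProfile]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


@_stage("import")
def read_inputs(inputs: Sequence[InputFile], polarity_hint: int = -1) -> List[Scan]:
    """Read every manifest entry into Scan records."""
    scans: List[Scan] = []
    for entry in inputs:
        fmt = entry.format or entry.path.suffix.lstrip(".").lower()
        if fmt == "mzxml":
            scans.extend(spectra_io.read_mzxml(entry.path, sample_id=entry.sample_id))
        elif fmt in ("csv", "dta"):
            if entry.mode == "pis":
                level = 2
            elif entry.mode == "nls":
                level = 2
            else:
                level = entry.ms_level
            meta = Scan(
                sample_id=entry.sample_id,
                ms_level=level,
                polarity=polarity_hint,
                mode=entry.mode,
                monitored_fragment_mz=entry.monitored if entry.mode == "pis" else None,
                neutral_loss_delta=entry.delta if entry.mode == "nls" else None,
                precursor_mz=entry.precursor_mz if level == 2 and entry.mode == "full" else None,
            )
            scans.append(spectra_io.read_peaklist(entry.path, fmt, meta))
        else:
            raise ValueError(f"unknown input format {fmt!r} for {entry.path}")
    logger.info("import: %d scans from %d files", len(scans), len(inputs))
    return scans


@_stage("transpose")
def transpose_scans(scans: Sequence[Scan], settings: MasterScanSettings) -> List[Scan]:
    """Replace PIS/NLS scans with their virtual MS/MS transpositions."""
    full = [s for s in scans if s.mode == "full"]
    pis = [s for s in scans if s.mode == "pis"]
    nls = [s for s in scans if s.mode == "nls"]
    out = list(full)
    if pis:
        virtual = scanmodes.transpose_pis(pis, settings.ms1_resolution)
        logger.info("transpose: %d PIS scans -> %d virtual MS/MS", len(pis), len(virtual))
        out.extend(virtual)
    if nls:
        virtual = scanmodes.transpose_nls(nls, settings.ms1_resolution)
        logger.info("transpose: %d NLS scans -> %d virtual MS/MS", len(nls), len(virtual))
        out.extend(virtual)
    return out


@_stage("build")
def build_stage(scans: Sequence[Scan], settings: MasterScanSettings) -> MasterScan:
    ms = build_masterscan(scans, settings)
    n_frag = sum(len(e.fragments) for e in ms.entries)
    logger.info(
        "build: %d precursor clusters (%d virtual), %d fragment clusters, %d samples",
        len(ms.entries),
        sum(1 for e in ms.entries if e.virtual),
        n_frag,
        len(ms.samples),
    )
    return ms


@_stage("query")
def query_stage(ms: MasterScan, asts: Sequence[QueryAst]) -> List[IdentificationRecord]:
    records = run_queries(asts, ms)
    logger.info("query: %d records from %d queries", len(records), len(asts))
    return records


@_stage("quantify")
def quantify_stage(
    records: Sequence[IdentificationRecord], ms: MasterScan
) -> Tuple[List[IdentificationRecord], List[quant.ClassProfile]]:
    corrected = quant.isotopic_correction(records, ms)
    profiles = quant.class_normalize(corrected)
    logger.info(
        "quantify: %d records corrected, %d class profiles", len(corrected), len(profiles)
    )
    return corrected, profiles


def write_profiles_csv(profiles: Sequence[quant.ClassProfile], path: str | Path) -> None:
    """Long-format profile table: class, species, sample, abundance."""
    import pandas as pd

    rows = []
    for p in profiles:
        for species, per_sample in p.entries.items():
            for sample in sorted(per_sample):
                rows.append(
                    {
                        "class": p.lipid_class,
                        "species": species,
                        "sample": sample,
                        "abundance": per_sample[sample],
                    }
                )
    pd.DataFrame(rows, columns=["class", "species", "sample", "abundance"]).to_csv(
        path, index=False
    )


def run_pipeline(
    config: ExperimentConfig, mfql_paths: Sequence[str | Path]
) -> PipelineResult:
    """Execute the full pipeline and write the configured outputs."""
    if not mfql_paths:
        raise RuntimeError("[query] no query scripts given")
    asts = [parse_mfql(Path(p).read_text()) for p in mfql_paths]
    polarity_hint = -1
    for ast in asts:
        pols = {pol for _, _, pol in ast.identify}
        if pols:
            polarity_hint = pols.pop()
            break
    scans = read_inputs(config.inputs, polarity_hint=polarity_hint)
    scans = transpose_scans(scans, config.settings)
    ms = build_stage(scans, config.settings)
    records = query_stage(ms, asts)
    records, profiles = quantify_stage(records, ms)
    spectra_io.write_results_csv(records, config.results_path)
    logger.info("report: wrote %s", config.results_path)
    if config.profiles_path:
        write_profiles_csv(profiles, config.profiles_path)
        logger.info("report: wrote %s", config.profiles_path)
    if config.masterscan_path:
        save_masterscan(ms, config.masterscan_path)
        logger.info("report: wrote %s", config.masterscan_path)
    return PipelineResult(masterscan=ms, records=records, profiles=profiles)


# ----------------------------------------------------------------------
# CLI
# ----------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log stage details to stderr.")
def main(verbose: bool) -> None:
    """Shotgun-lipidomics spectra interpretation."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(name)s %(levelname)s %(message)s",
    )


def _fail(exc: Exception) -> None:
    raise click.ClickException(str(exc))


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--queries", "query_paths", multiple=True, required=True,
              type=click.Path(exists=True))
@click.option("--out", "out_path", default=None, type=click.Path())
def run(config_path: str, query_paths: Tuple[str, ...], out_path: Optional[str]) -> None:
    """Run the full pipeline: import, transpose, build, query, report."""
    try:
        config = ExperimentConfig.from_toml(config_path)
        if out_path:
            config.results_path = Path(out_path)
        result = run_pipeline(config, list(query_paths))
    except Exception as exc:
        _fail(exc)
    click.echo(f"{len(result.records)} records -> {config.results_path}")


@main.command()
@click.option("--seed", default=0, type=int)
@click.option("--classes", default="PE,PG")
@click.option("--n-species", default=20, type=int)
@click.option("--mode", default="dda", type=click.Choice(["dda", "pis", "nls"]))
@click.option("--replicates", default=4, type=int)
@click.option("--mass-error-ppm", default=0.0, type=float)
@click.option("--intensity-noise", default=0.0, type=float)
@click.option("--out-dir", default="simulated", type=click.Path())
def simulate(seed, classes, n_species, mode, replicates, mass_error_ppm,
             intensity_noise, out_dir) -> None:
    """Simulate a shotgun dataset with a known lipidome."""
    try:
        class_list = [c.strip() for c in classes.split(",") if c.strip()]
        lip = synthgen.generate_lipidome(class_list, n_species, seed)
        inst = synthgen.InstrumentModel(
            mass_error_ppm=mass_error_ppm, intensity_noise=intensity_noise
        )
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: List[str] = []
        if mode == "dda":
            scans = synthgen.simulate_dda(lip, inst, replicates, seed)
            by_sample: Dict[str, List[Scan]] = {}
            for s in scans:
                by_sample.setdefault(s.sample_id, []).append(s)
            for sid, ss in sorted(by_sample.items()):
                fname = f"{sid}.mzXML"
                spectra_io.write_mzxml(ss, out / fname)
                manifest.append(
                    f'[[inputs]]\npath = "{fname}"\nsample_id = "{sid}"\nmode = "full"\n'
                )
        else:
            if mode == "pis":
                targets = synthgen.pis_targets_for(lip)
                scans = synthgen.simulate_pis(lip, targets, inst, replicates, seed)
            else:
                deltas = sorted(
                    {round(LIPID_CLASSES[c].positive_loss_mass, 2) for c in class_list}
                )
                scans = synthgen.simulate_nls(lip, deltas, inst, replicates, seed)
            for i, s in enumerate(scans):
                fname = f"{s.sample_id}_scan{i:03d}.csv"
                with open(out / fname, "w") as fh:
                    for p in s.peaks:
                        fh.write(f"{p.mz:.6f},{p.intensity:.6f}\n")
                extra = (
                    f"monitored = {s.monitored_fragment_mz}\n"
                    if mode == "pis"
                    else f"delta = {s.neutral_loss_delta}\n"
                )
                manifest.append(
                    f'[[inputs]]\npath = "{fname}"\nsample_id = "{s.sample_id}"\n'
                    f'mode = "{mode}"\n{extra}'
                )
        truth = out / "lipidome.txt"
        truth.write_text(
            "".join(
                f"{sp.molecular_annotation}\t{sp.abundance:.2f}\n"
                for sp in lip.species
            )
        )
        (out / "experiment.toml").write_text(
            f"seed = {seed}\n\n" + "\n".join(manifest)
        )
        click.echo(f"{len(lip.species)} species, {mode} dataset -> {out}")
    except Exception as exc:
        _fail(exc)


@main.command(name="import")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--polarity", default=-1, type=int)
def import_(config_path: str, out_path: str, polarity: int) -> None:
    """Read the manifest's spectra into a scan container."""
    try:
        config = ExperimentConfig.from_toml(config_path)
        scans = read_inputs(config.inputs, polarity_hint=polarity)
        spectra_io.save_scans(scans, out_path)
    except Exception as exc:
        _fail(exc)
    click.echo(f"{len(scans)} scans -> {out_path}")


@main.command()
@click.option("--scans", "scans_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--r0", default=7500.0, type=float)
@click.option("--mref", default=700.0, type=float)
def transpose(scans_path: str, out_path: str, r0: float, mref: float) -> None:
    """Transpose PIS/NLS scans in a container into virtual MS/MS scans."""
    try:
        scans = spectra_io.load_scans(scans_path)
        settings = MasterScanSettings(
            ms1_resolution=ResolutionModel(r0=r0, m_ref=mref)
        )
        out = transpose_scans(scans, settings)
        spectra_io.save_scans(out, out_path)
    except Exception as exc:
        _fail(exc)
    click.echo(f"{len(out)} scans -> {out_path}")


@main.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--scans", "scans_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def build(config_path: str, scans_path: str, out_path: str) -> None:
    """Build a MasterScan from a scan container."""
    try:
        config = ExperimentConfig.from_toml(config_path)
        scans = spectra_io.load_scans(scans_path)
        scans = transpose_scans(scans, config.settings)
        ms = build_stage(scans, config.settings)
        save_masterscan(ms, out_path)
    except Exception as exc:
        _fail(exc)
    click.echo(f"{len(ms.entries)} precursor clusters -> {out_path}")


@main.command()
@click.option("--masterscan", "ms_path", required=True, type=click.Path(exists=True))
@click.option("--queries", "query_paths", multiple=True, required=True,
              type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--correct/--no-correct", default=True,
              help="Apply isotopic correction before writing.")
def query(ms_path: str, query_paths: Tuple[str, ...], out_path: str, correct: bool) -> None:
    """Run query scripts against a saved MasterScan."""
    try:
        ms = load_masterscan(ms_path)
        asts = [parse_mfql(Path(p).read_text()) for p in query_paths]
        records = query_stage(ms, asts)
        if correct:
            records = quant.isotopic_correction(records, ms)
        spectra_io.write_results_csv(records, out_path)
    except Exception as exc:
        _fail(exc)
    click.echo(f"{len(records)} records -> {out_path}")


@main.command()
@click.option("--results", "results_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def report(results_path: str, out_path: str) -> None:
    """Normalize a results table into per-class relative profiles."""
    import pandas as pd

    try:
        frame = pd.read_csv(results_path)
        sample_cols = [c for c in frame.columns if c.startswith("intensity:")]
        if not sample_cols:
            raise ValueError("results table has no intensity columns")
        rows = []
        grouped = frame.groupby(["query", "species"], sort=True)[sample_cols].sum()
        for cls, sub in grouped.groupby(level="query", sort=True):
            totals = sub.sum(axis=0)
            for (q, species), values in sub.iterrows():
                for col in sample_cols:
                    total = totals[col]
                    rows.append(
                        {
                            "class": q,
                            "species": species,
                            "sample": col.split(":", 1)[1],
                            "abundance": values[col] / total if total > 0 else float("nan"),
                        }
                    )
        pd.DataFrame(rows, columns=["class", "species", "sample", "abundance"]).to_csv(
            out_path, index=False
        )
    except Exception as exc:
        _fail(exc)
    click.echo(f"profiles -> {out_path}")


if __name__ == "__main__":
    main()
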