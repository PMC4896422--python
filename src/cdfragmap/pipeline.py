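"""End-to-end analysis pipeline: spectra → fractions → segments → map →
fragment consensus → difference regions → construct QC.

Driven by a flat YAML config (see :class:`RunConfig`).  Stage order is
fixed: preprocess → deconvolve each construct → estimate segment counts →
localize segments on each sequence → trim fragment edges and build the
consensus map → difference-spectrum region fits → QC (melt curves, SEC).
Every stage logs a structured record; any stage failure aborts with the
stage name and the offending input id.  Given one config and seed the
report is byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .consensus import (DEFAULT_EDGE_TRIM, FragmentDef, consensus_map,
                        load_fragment_table, region_fractions)
from .deconvolution import (FitOptions, ReferenceSet, estimate_segment_counts,
                            fit_fractions)
from .localization import (assign_segments, fractions_from_map,
                           max_component_shift)
from .qc import classify_oligomer, estimate_tm, load_melt_curve, load_sec_table, sec_calibrate
from .spectra import load_spectrum

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cdfragmap")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {input_id!r}: {cause}")
        self.stage = stage
        self.input_id = input_id
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration (flat YAML keys).

    Required keys: ``parent_spectrum``, ``fasta``, ``fragment_table``,
    ``fragment_spectra_dir``, ``reference_dir``, ``out_dir``.  Optional:
    ``trim`` (default 5), ``seed`` (default 0), ``melt_curve_dir``,
    ``sec_standards``, ``sec_samples``, ``difference_pairs`` (list of
    [larger_id, smaller_id] construct pairs, 'parent' allowed).
    """

    parent_spectrum: Path
    fasta: Path
    fragment_table: Path
    fragment_spectra_dir: Path
    reference_dir: Path
    out_dir: Path
    trim: int = DEFAULT_EDGE_TRIM
    seed: int = 0
    melt_curve_dir: Path | None = None
    sec_standards: Path | None = None
    sec_samples: Path | None = None
    difference_pairs: list[tuple[str, str]] = field(default_factory=list)
    fit_options: FitOptions = field(default_factory=FitOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(key: str, required: bool = True) -> Path | None:
            if key not in raw or raw[key] is None:
                if required:
                    raise ValueError(f"config is missing required key {key!r}")
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base / p

        cfg = cls(
            parent_spectrum=resolve("parent_spectrum"),
            fasta=resolve("fasta"),
            fragment_table=resolve("fragment_table"),
            fragment_spectra_dir=resolve("fragment_spectra_dir"),
            reference_dir=resolve("reference_dir"),
            out_dir=resolve("out_dir"),
            trim=int(raw.get("trim", DEFAULT_EDGE_TRIM)),
            seed=int(raw.get("seed", 0)),
            melt_curve_dir=resolve("melt_curve_dir", required=False),
            sec_standards=resolve("sec_standards", required=False),
            sec_samples=resolve("sec_samples", required=False),
            difference_pairs=[tuple(p) for p in raw.get("difference_pairs", [])],
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.trim < 0:
            raise ValueError("trim must be >= 0")
        for name in ("parent_spectrum", "fasta", "fragment_table",
                     "fragment_spectra_dir", "reference_dir",
                     "melt_curve_dir", "sec_standards", "sec_samples"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name}: {p} does not exist")


def _stage(name: str, input_id: str):
    """Context helper: time a stage and wrap failures."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage=%s input=%s elapsed=%.3fs error=%s",
                          name, input_id, elapsed, exc)
                raise PipelineError(name, input_id, exc) from exc
            log.info("stage=%s input=%s elapsed=%.3fs ok", name, input_id, elapsed)
            return False
    return _Ctx()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the report dict and writes
    ``report.json`` plus per-construct map TSVs under ``cfg.out_dir``."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and getattr(h, "stream", None) is sys.stderr
               for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))

    try:
        return _run(cfg, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out_dir: Path) -> dict:
    report: dict = {"config": {"trim": cfg.trim, "seed": cfg.seed}}

    with _stage("load", "reference_set"):
        refs = ReferenceSet.from_directory(cfg.reference_dir)
    with _stage("load", "sequences"):
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cfg.fasta), "fasta")}
        if "parent" not in seqs:
            raise ValueError("FASTA must contain a record named 'parent'")
    with _stage("load", "fragment_table"):
        frags = load_fragment_table(cfg.fragment_table)

    constructs = {"parent": (load_spectrum(cfg.parent_spectrum, "delta_epsilon",
                                           "parent"), seqs["parent"], None)}
    for frag in frags:
        with _stage("load", frag.id):
            spec = load_spectrum(Path(cfg.fragment_spectra_dir) / f"{frag.id}.txt",
                                 "delta_epsilon", frag.id)
            seq = seqs.get(frag.id,
                           seqs["parent"][frag.start - 1:frag.end])
            constructs[frag.id] = (spec, seq, frag)

    maps = {}
    report["constructs"] = {}
    for cid, (spec, seq, frag) in constructs.items():
        with _stage("fit_fractions", cid):
            fractions, result = fit_fractions(spec, refs, cfg.fit_options)
        with _stage("segment_counts", cid):
            counts = estimate_segment_counts(fractions, len(seq))
        with _stage("assign_segments", cid):
            rmap = assign_segments(seq, fractions, counts, strict=False)
            maps[cid] = rmap
            rmap.to_tsv(out_dir / f"map_{cid}.tsv", seq)
        implied = fractions_from_map(rmap)
        report["constructs"][cid] = {
            "fractions": fractions.as_dict(),
            "spectral_rmsd": round(result.spectral_rmsd, 6),
            "kept_ranks": result.kept_ranks,
            "n_alpha": counts.n_alpha,
            "n_beta": counts.n_beta,
            "map": rmap.run_length_string(),
            "max_component_shift": round(max_component_shift(fractions, implied), 6),
            "native": frag.native_flag if frag else True,
        }

    with _stage("consensus", "all"):
        pairs = [(frag, maps[frag.id]) for frag in frags]
        cons, coverage = consensus_map(maps["parent"], pairs, cfg.trim)
        cons.to_tsv(out_dir / "map_consensus.tsv", seqs["parent"])
        report["consensus"] = {
            "map": cons.run_length_string(),
            "fractions": fractions_from_map(cons).as_dict(),
            "mean_coverage": float(coverage.mean()),
            "max_coverage": int(coverage.max()),
        }

    report["difference_regions"] = {}
    frag_by_id = {f.id: f for f in frags}
    for big_id, small_id in cfg.difference_pairs:
        key = f"{big_id}-minus-{small_id}"
        with _stage("difference_region", key):
            big_spec, big_seq, big_frag = constructs[big_id]
            small_spec, small_seq, small_frag = constructs[small_id]
            fit = region_fractions(
                big_spec, len(big_seq), small_spec, len(small_seq), refs,
                parent_native=big_frag.native_flag if big_frag else True,
                frag_native=small_frag.native_flag if small_frag else True,
                options=cfg.fit_options,
            )
            report["difference_regions"][key] = {
                "n_region": fit.n_region,
                "fractions": fit.fractions.as_dict(),
                "valid": fit.valid,
                "warnings": fit.warnings,
            }

    report["qc"] = {}
    if cfg.melt_curve_dir is not None:
        melts = {}
        for path in sorted(Path(cfg.melt_curve_dir).glob("*.tsv")):
            with _stage("estimate_tm", path.stem):
                res = estimate_tm(load_melt_curve(path))
                melts[path.stem] = {
                    "tm": None if res.tm is None else round(res.tm, 2),
                    "verdict": res.verdict,
                }
        report["qc"]["melting"] = melts
    if cfg.sec_standards is not None:
        with _stage("sec_calibrate", "standards"):
            rows = load_sec_table(cfg.sec_standards) if _is_qc_table(cfg.sec_standards) \
                else None
            standards = _load_standards(cfg.sec_standards)
            calib = sec_calibrate(standards)
            report["qc"]["sec_calibration"] = {
                "a": calib.a, "b": calib.b, "r_squared": calib.r_squared,
            }
        if cfg.sec_samples is not None:
            oligo = {}
            for row in load_sec_table(cfg.sec_samples):
                with _stage("classify_oligomer", row["id"]):
                    if row["m_app"] is None or row["m_calc"] is None:
                        oligo[row["id"]] = {"status": "not determined"}
                        continue
                    call = classify_oligomer(row["m_app"], row["m_calc"])
                    oligo[row["id"]] = {"status": call.status,
                                        "ratio": round(call.ratio, 3)}
            report["qc"]["oligomer"] = oligo

    with _stage("write_report", "report.json"):
        with (out_dir / "report.json").open("w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _is_qc_table(path: Path) -> bool:
    with Path(path).open() as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if text:
                return text.split()[0].lower() == "id"
    return False


def _load_standards(path: Path) -> list[tuple[float, float]]:
    standards = []
    with Path(path).open() as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if not parts[0][0].isdigit():
                continue
            standards.append((float(parts[0]), float(parts[1])))
    return standards
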