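"""End-to-end orchestration: simulate → preprocess → ldaep → stats.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name, so a run is reproducible bit-for-bit from its
config.  A JSON run manifest records the stage order, per-stage output
hashes, and per-subject exclusion counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ldaep_lab.cohort import CohortSpec, GroupSpec, generate_cohort
from ldaep_lab.io import (
    load_epochs,
    read_bids_subject,
    read_channels_tsv,
    read_events_tsv,
    save_epochs,
    write_bids_subject,
)
from ldaep_lab.ldaep import ldaep_from_epochs, ldaep_table
from ldaep_lab.paradigm import ConfigurationError, ParadigmSpec, generate_paradigm
from ldaep_lab.preprocessing import PreprocConfig, preprocess_recording
from ldaep_lab.simulate import simulate_recording
from ldaep_lab.stats import render_report, run_group_analysis

__all__ = ["RunConfig", "RunManifest", "run_all", "validate_dataset", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "ldaep_run"
    seed: int = 0
    montage: str = "default8"
    fs: float = 2048.0
    channel: str = "Cz"
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocConfig = field(default_factory=PreprocConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        kwargs = {}
        for key in ("out_dir", "seed", "montage", "fs", "channel"):
            if key in raw:
                kwargs[key] = raw[key]
        if "paradigm" in raw:
            p = dict(raw["paradigm"])
            for tup in ("intensities_db", "isi_range_ms"):
                if tup in p:
                    p[tup] = tuple(p[tup])
            kwargs["paradigm"] = ParadigmSpec(**p)
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "groups" in c:
                c["groups"] = {
                    g: GroupSpec(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in gs.items()})
                    for g, gs in c["groups"].items()
                }
            kwargs["cohort"] = CohortSpec(**c)
        if "preprocess" in raw:
            pp = dict(raw["preprocess"])
            for tup in ("bandpass", "epoch_window_s"):
                if tup in pp:
                    pp[tup] = tuple(pp[tup])
            kwargs["preprocess"] = PreprocConfig(**pp)
        return cls(**kwargs)


@dataclass
class RunManifest:
    stage_order: list[str] = field(default_factory=list)
    hashes: dict[str, str] = field(default_factory=dict)
    exclusions: dict[str, dict] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)
    version: str = ""

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_dataset(config: RunConfig) -> Path:
    """Simulate the cohort and write the BIDS-style dataset."""
    out = Path(config.out_dir)
    bids = out / "bids"
    bids.mkdir(parents=True, exist_ok=True)
    total_n = sum(g.n for g in config.cohort.groups.values())
    if total_n < 1:
        raise ConfigurationError("cohort has zero subjects")

    cohort_spec = dataclasses.replace(
        config.cohort, seed=stage_seed(config.seed, "cohort"))
    profiles, table = generate_cohort(cohort_spec)
    truth_cols = [c for c in table.columns if c.startswith("true_")]
    table.drop(columns=truth_cols).to_csv(out / "cohort.csv", index=False)
    # ground truth kept separate and never read by the pipeline
    table[["subject_id", *truth_cols]].to_csv(out / "ground_truth.csv", index=False)

    for i, prof in enumerate(profiles):
        par = dataclasses.replace(
            config.paradigm, seed=stage_seed(config.seed, f"paradigm:{prof.subject_id}"))
        events = generate_paradigm(par)
        rec = simulate_recording(
            prof, events, fs=config.fs, montage=config.montage,
            seed=stage_seed(config.seed, f"recording:{prof.subject_id}"))
        write_bids_subject(rec, bids, prof.subject_id)
    return bids


def preprocess_dataset(config: RunConfig, bids_dir: Path | None = None) -> Path:
    out = Path(config.out_dir)
    bids = bids_dir or out / "bids"
    epo_dir = out / "epochs"
    epo_dir.mkdir(parents=True, exist_ok=True)
    logs = {}
    for sub_dir in sorted(bids.glob("sub-*")):
        sid = sub_dir.name
        rec = read_bids_subject(bids, sid)
        es, report = preprocess_recording(rec, config.preprocess, subject_id=sid)
        save_epochs(es, epo_dir / f"{sid}_epochs")
        logs[sid] = report
    with open(epo_dir / "preprocess_log.json", "w") as fh:
        json.dump(logs, fh, indent=2)
    return epo_dir


def ldaep_dataset(config: RunConfig, epochs_dir: Path | None = None) -> Path:
    out = Path(config.out_dir)
    epo_dir = epochs_dir or out / "epochs"
    results = []
    for meta in sorted(epo_dir.glob("sub-*_epochs.json")):
        es = load_epochs(meta.with_suffix(""))
        results.append(ldaep_from_epochs(es, channel=config.channel))
    cohort_path = out / "cohort.csv"
    cohort = pd.read_csv(cohort_path) if cohort_path.exists() else None
    table = ldaep_table(results, cohort)
    ldir = out / "ldaep"
    ldir.mkdir(parents=True, exist_ok=True)
    table.to_csv(ldir / "ldaep_table.csv", index=False)
    return ldir


def stats_dataset(config: RunConfig, ldaep_dir: Path | None = None) -> Path:
    out = Path(config.out_dir)
    ldir = ldaep_dir or out / "ldaep"
    table = pd.read_csv(ldir / "ldaep_table.csv")
    tables = run_group_analysis(table)
    sdir = out / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    for name, tab in tables.items():
        tab.to_csv(sdir / f"{name}.csv", index=False)
    (sdir / "report.txt").write_text(render_report(tables))
    return sdir


def run_all(config: RunConfig) -> RunManifest:
    """Run the full pipeline; returns the saved manifest."""
    from ldaep_lab import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__)

    for stage, fn in (
        ("simulate", lambda: simulate_dataset(config)),
        ("preprocess", lambda: preprocess_dataset(config)),
        ("ldaep", lambda: ldaep_dataset(config)),
        ("stats", lambda: stats_dataset(config)),
    ):
        try:
            stage_out = fn()
        except Exception:
            manifest.stage_order.append(f"{stage}:FAILED")
            manifest.save(out / "manifest.json")
            raise
        manifest.stage_order.append(stage)
        manifest.timestamps[stage] = time.time()
        for f in sorted(Path(stage_out).rglob("*")):
            if f.is_file():
                manifest.hashes[str(f.relative_to(out))] = _hash_file(f)

    log_path = out / "epochs" / "preprocess_log.json"
    if log_path.exists():
        with open(log_path) as fh:
            manifest.exclusions = json.load(fh)
    manifest.save(out / "manifest.json")
    return manifest


def validate_dataset(path: str | Path,
                     valid_intensities: tuple[float, ...] = (55, 65, 75, 85, 95)
                     ) -> list[dict]:
    """Consistency checks on a BIDS-style dataset; returns machine-readable
    findings (empty list = clean)."""
    path = Path(path)
    findings: list[dict] = []
    if not path.exists():
        return [dict(file=str(path), check="exists", message="path does not exist")]
    subs = sorted(path.glob("sub-*"))
    if not subs:
        findings.append(dict(file=str(path), check="layout",
                             message="no sub-* directories found"))
    for sub in subs:
        eeg_dir = sub / "eeg"
        edfs = list(eeg_dir.glob("*_eeg.edf"))
        if not edfs:
            findings.append(dict(file=str(sub), check="layout", message="no EDF file"))
            continue
        edf = edfs[0]
        stem = edf.name[:-len("_eeg.edf")]
        try:
            rec = read_bids_subject(path, sub.name)
        except Exception as exc:
            findings.append(dict(file=str(edf), check="readable",
                                 message=f"unreadable EDF: {exc}"))
            continue
        ch_path = eeg_dir / f"{stem}_channels.tsv"
        if ch_path.exists():
            ch = read_channels_tsv(ch_path)
            if list(ch["name"]) != rec.channel_labels:
                findings.append(dict(file=str(ch_path), check="channels",
                                     message="channel list mismatch with EDF"))
            fs_tsv = float(ch["sampling_frequency"].iloc[0])
            if abs(fs_tsv - rec.fs) > 1e-6:
                findings.append(dict(file=str(ch_path), check="sampling_rate",
                                     message=f"fs mismatch: tsv {fs_tsv} vs edf {rec.fs}"))
        ev_path = eeg_dir / f"{stem}_events.tsv"
        if ev_path.exists():
            ev = read_events_tsv(ev_path)
            bad = set(ev.intensity_db) - set(float(v) for v in valid_intensities)
            if bad:
                findings.append(dict(file=str(ev_path), check="events",
                                     message=f"unknown intensity labels: {sorted(bad)}"))
            if ev.onsets_s[-1] > rec.duration_s:
                findings.append(dict(file=str(ev_path), check="events",
                                     message="events extend past the recording"))
    return findings
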