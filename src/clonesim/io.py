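"""File formats: lineage TSV, FASTA, YAML configuration, run manifest.

Record naming follows the simulator's conventions: the naive root sequence is
written as ``Psi_hat`` and sampled cells as ``Psi_1``..``Psi_s``.  Times are
days throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .bdt import EVENT_NAMES, Genealogy
from .am import AMConfig, AMRunResult, materialize_sequence
from .shm import MutationEvent, decode_dna, load_fivemer_table

__all__ = [
    "ROOT_RECORD_ID",
    "write_lineage",
    "read_lineage",
    "write_sampled_fasta",
    "read_fasta",
    "write_series",
    "write_stage_log",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "write_manifest",
]

ROOT_RECORD_ID = "Psi_hat"

_EVENT_CODES = {v: k for k, v in EVENT_NAMES.items()}


# ---------------------------------------------------------------------------
# Lineage table
# ---------------------------------------------------------------------------

_LINEAGE_COLS = ["cell_id", "parent_id", "birth_time", "end_time", "end_event",
                 "g", "n_mut_from_parent", "mutations", "sampled_label"]


def write_lineage(result: AMRunResult, labels: dict[str, int], path) -> None:
    """One TSV row per cell, topologically ordered (parent before child)."""
    by_entity = {eid: lab for lab, eid in labels.items()}
    gen = result.genealogy
    with open(path, "w") as fh:
        fh.write("\t".join(_LINEAGE_COLS) + "\n")
        for eid in range(len(gen)):
            muts = result.muts[eid] or ()
            fh.write("\t".join([
                str(eid),
                str(gen.parent[eid]),
                format(gen.birth_time[eid], ".10g"),
                "" if gen.end_time[eid] is None else format(gen.end_time[eid], ".10g"),
                EVENT_NAMES[gen.end_event[eid]],
                str(result.g[eid]),
                str(len(muts)),
                ";".join(m.as_str() for m in muts),
                by_entity.get(eid, ""),
            ]) + "\n")


def read_lineage(path) -> tuple[Genealogy, list[int], list, dict[str, int]]:
    """Inverse of :func:`write_lineage`: (genealogy, g flags, muts, labels)."""
    gen = Genealogy()
    g: list[int] = []
    muts: list = []
    labels: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LINEAGE_COLS:
            raise ValueError(f"expected lineage columns {_LINEAGE_COLS}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            (cid, pid, bt, et, ee, gg, nm, mstr, lab) = line.rstrip("\n").split("\t")
            eid = gen.append(None if int(pid) < 0 else int(pid), float(bt))
            if eid != int(cid):
                raise ValueError("lineage rows must be topologically ordered by cell_id")
            if et:
                gen.close(eid, float(et), _EVENT_CODES[ee])
            g.append(int(gg))
            events = [MutationEvent.from_str(s) for s in mstr.split(";") if s]
            if len(events) != int(nm):
                raise ValueError(f"cell {cid}: mutation count mismatch")
            muts.append(events or None)
            if lab:
                labels[lab] = eid
    return gen, g, muts, labels


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_sampled_fasta(result: AMRunResult, labels: dict[str, int], path) -> None:
    """Root record (Psi_hat) followed by the sampled cells, Psi_k order."""
    records = [SeqRecord(Seq(result.config.root_sequence), id=ROOT_RECORD_ID, description="")]
    for lab in sorted(labels, key=lambda s: int(s.rsplit("_", 1)[1])):
        seq = decode_dna(materialize_sequence(result, labels[lab]))
        records.append(SeqRecord(Seq(seq), id=lab, description=""))
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


# ---------------------------------------------------------------------------
# Time series and stage log
# ---------------------------------------------------------------------------

def write_series(result: AMRunResult, path) -> None:
    mean_aff = result.mean_activated_affinity()
    with open(path, "w") as fh:
        fh.write("t\tround\tstage\tn_activated\tn_memory\tsigma\tmean_activated_affinity\n")
        for row, ma in zip(result.series, mean_aff):
            t, rnd, stage, na, nm, sigma = row
            stage_name = "infected" if stage == 1.0 else "dormant"
            fh.write(f"{t:.6g}\t{int(rnd)}\t{stage_name}\t{int(round(na))}\t"
                     f"{int(round(nm))}\t{sigma:.10g}\t"
                     f"{'' if np.isnan(ma) else format(ma, '.10g')}\n")


def write_stage_log(result: AMRunResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("round\tt_begin\tt_end\tduration\tsigma_end\tn_activated_end\tn_memory_end\n")
        for rs in result.rounds:
            fh.write(f"{rs.round}\t{rs.t_begin:.6g}\t{rs.t_end:.6g}\t{rs.duration:.6g}\t"
                     f"{rs.sigma_end:.10g}\t{rs.n_activated_end}\t{rs.n_memory_end}\n")


# ---------------------------------------------------------------------------
# Configuration (YAML, Table-style parameter names)
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "lambda_b": "lambda_b", "lambda_d": "lambda_d", "lambda_d_prime": "lambda_dp",
    "lambda_t": "lambda_t", "rho_p": "rho_p", "rho_m": "rho_m", "rho_a": "rho_a",
    "A": "A", "w_f": "w_f", "kappa": "kappa", "mu": "mu", "L": "L",
    "Delta_0": "Delta_0", "Delta_0_prime": "Delta_0p", "C": "C", "M": "M",
    "r": "r", "switch_rule": "switch_rule", "infected_duration": "infected_duration",
    "sample_size": "sample_size", "max_infected_days": "max_infected_days",
    "max_events": "max_events", "ts_interval": "ts_interval",
    "root_sequence": "root_sequence",
}


def config_to_dict(cfg: AMConfig) -> dict:
    out = {k: getattr(cfg, attr) for k, attr in _CONFIG_KEYS.items()}
    out["CDR"] = [list(rng) for rng in cfg.cdr]
    out["t_start"] = list(cfg.t_start)
    out["targets"] = list(cfg.targets) if cfg.targets is not None else None
    return out


def config_from_dict(data: dict) -> AMConfig:
    kwargs = {}
    for key, value in data.items():
        if key == "CDR":
            kwargs["cdr"] = tuple(tuple(x) for x in value)
        elif key == "t_start":
            kwargs["t_start"] = tuple(float(x) for x in value)
        elif key == "targets":
            kwargs["targets"] = tuple(value) if value is not None else None
        elif key == "fivemer_table":
            if value:
                kwargs["fivemer_table"] = load_fivemer_table(value)
        elif key in _CONFIG_KEYS:
            kwargs[_CONFIG_KEYS[key]] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    cfg = AMConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> AMConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a mapping")
    return config_from_dict(data)


def save_config(cfg: AMConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def write_manifest(result: AMRunResult, seed: int, outputs: dict[str, str], path) -> None:
    doc = {
        "software": {"name": "clonesim", "version": __version__},
        "seed": seed,
        "stop_reason": result.reason,
        "n_events": result.n_events,
        "rounds": [asdict(rs) for rs in result.rounds],
        "outputs": outputs,
        "config": config_to_dict(result.config),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=float)
        fh.write("\n")
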