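"""Delimited-text readers/writers shared by the CLI and the generators.

All tables are long-format CSV/TSV with unit-bearing column names
(``c_flux_mmol_m2_d``, ``u10_m_s`` …) so unit errors stay greppable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .gas_exchange import WindRecord
from .placement import PeptideObservation, PlacementRead
from .productivity import TripleOxygenSample
from .stoich import TrapFlux

__all__ = [
    "write_wind_csv",
    "read_wind_csv",
    "write_trap_csv",
    "read_trap_csv",
    "write_toi_csv",
    "read_toi_csv",
    "write_placement_tsv",
    "write_jplace",
    "write_peptides_tsv",
    "read_peptides_tsv",
    "write_ground_truth",
]


def write_wind_csv(records: Sequence[WindRecord], path) -> None:
    pd.DataFrame({"date": [r.date for r in records], "u10_m_s": [r.u10 for r in records]}).to_csv(
        path, index=False
    )


def read_wind_csv(path) -> list[WindRecord]:
    df = pd.read_csv(path)
    return [WindRecord(date=str(r.date), u10=float(r.u10_m_s)) for r in df.itertuples(index=False)]


def write_trap_csv(traps: Sequence[TrapFlux], path) -> None:
    pd.DataFrame(
        {
            "depth_m": [t.depth for t in traps],
            "c_flux_mmol_m2_d": [t.c_flux for t in traps],
            "n_flux_umol_m2_d": [t.n_flux for t in traps],
        }
    ).to_csv(path, index=False)


def read_trap_csv(path) -> list[TrapFlux]:
    df = pd.read_csv(path)
    return [
        TrapFlux(depth=float(r.depth_m), c_flux=float(r.c_flux_mmol_m2_d), n_flux=float(r.n_flux_umol_m2_d))
        for r in df.itertuples(index=False)
    ]


def write_toi_csv(samples: Sequence[TripleOxygenSample], path) -> None:
    pd.DataFrame(
        {
            "station": [s.station for s in samples],
            "date": [s.date for s in samples],
            "delta17_per_mil": [s.delta17 for s in samples],
            "delta18_per_mil": [s.delta18 for s in samples],
            "o2ar_supersat": [s.o2ar_supersat for s in samples],
            "sigma_delta17": [s.sigma_delta17 for s in samples],
            "sigma_delta18": [s.sigma_delta18 for s in samples],
            "sigma_o2ar": [s.sigma_o2ar for s in samples],
        }
    ).to_csv(path, index=False)


def read_toi_csv(path) -> list[TripleOxygenSample]:
    df = pd.read_csv(path)
    return [
        TripleOxygenSample(
            station=str(r.station),
            date=str(r.date),
            delta17=float(r.delta17_per_mil),
            delta18=float(r.delta18_per_mil),
            o2ar_supersat=float(r.o2ar_supersat),
            sigma_delta17=float(r.sigma_delta17),
            sigma_delta18=float(r.sigma_delta18),
            sigma_o2ar=float(r.sigma_o2ar),
        )
        for r in df.itertuples(index=False)
    ]


def write_placement_tsv(reads: Sequence[PlacementRead], path) -> None:
    pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "gene": [r.gene for r in reads],
            "clade": [r.clade for r in reads],
            "branch_length": [r.branch_length for r in reads],
            "read_len_nt": [r.read_len for r in reads],
            "sample_id": [r.sample_id for r in reads],
            "weight": [r.weight for r in reads],
            "paired": [r.paired for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)


def write_jplace(
    reads: Sequence[PlacementRead], clade_to_edge: dict[str, int], path
) -> None:
    """Emit a jplace-compatible JSON document for the given reads.

    The reference tree is a placeholder; edge numbers come from the
    clade→edge map, and the pendant branch length carries the read's
    branch length.
    """
    placements = [
        {
            "p": [[clade_to_edge[r.clade], 0.0, r.weight, 0.0, r.branch_length]],
            "n": [r.read_id],
        }
        for r in reads
    ]
    doc = {
        "version": 3,
        "tree": "();",
        "fields": ["edge_num", "likelihood", "like_weight_ratio", "distal_length", "pendant_length"],
        "placements": placements,
        "metadata": {"invocation": "odzflux synthetic generator"},
    }
    Path(path).write_text(json.dumps(doc))


def write_peptides_tsv(obs: Sequence[PeptideObservation], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in obs],
            "peptide": [o.peptide for o in obs],
            "taxon": [o.taxon for o in obs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_peptides_tsv(path) -> list[PeptideObservation]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideObservation(sample_id=str(r.sample_id), peptide=str(r.peptide), taxon=str(r.taxon))
        for r in df.itertuples(index=False)
    ]


def write_ground_truth(truth: dict, path) -> None:
    """Sidecar YAML carrying the generator's ground truth."""
    Path(path).write_text(yaml.safe_dump(truth, sort_keys=True))
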