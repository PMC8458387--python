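"""Readers and writers: PDB/mmCIF C-alpha extraction (gemmi), FASTA
(Biopython), denaturation-curve tables (pandas) and idealised-model PDB
output, plus the run configuration shared by the CLI stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry import BladeSet, CoordinateModel
from .stability import DenaturationCurve

__all__ = [
    "EmptyModelError",
    "read_structure_calpha",
    "write_model_pdb",
    "read_fasta",
    "write_fasta",
    "read_curve_table",
    "write_curve_table",
    "profile_to_frame",
    "RunConfig",
]


class EmptyModelError(ValueError):
    """Structure file contains no polymer C-alpha atoms."""


def read_structure_calpha(path: str | Path, chains: Sequence[str] | None = None) -> CoordinateModel:
    """Read C-alpha records from a PDB or mmCIF file (format sniffed).

    First model only; for alternate locations the highest-occupancy
    conformer wins, ties broken by altloc label.  HETATM-only files raise
    EmptyModelError.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    model = st[0]
    chain_ids, resnums, icodes, resnames, coords = [], [], [], [], []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            if residue.het_flag == "H":
                info = gemmi.find_tabulated_residue(residue.name)
                if info is None or not info.is_amino_acid():
                    continue
            cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
            if not cas:
                continue
            # altloc policy: occupancy first, then altloc label
            ca = sorted(cas, key=lambda a: (-a.occ, a.altloc))[0]
            chain_ids.append(chain.name)
            resnums.append(residue.seqid.num)
            icodes.append((residue.seqid.icode or " ").strip())
            resnames.append(residue.name)
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not coords:
        raise EmptyModelError(f"no polymer C-alpha atoms found in {path}")
    return CoordinateModel(
        chain=np.array(chain_ids),
        resnum=np.array(resnums),
        icode=np.array(icodes),
        resname=np.array(resnames),
        coords=np.array(coords),
    )


def write_model_pdb(model: CoordinateModel, path: str | Path) -> None:
    """Write a C-alpha-only model as PDB (one atom per residue)."""
    st = gemmi.Structure()
    st.name = "bladekit-model"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for i in range(len(model)):
        ch = str(model.chain[i])
        if ch not in chains:
            chains[ch] = gemmi.Chain(ch)
        res = gemmi.Residue()
        res.name = str(model.resname[i])
        res.seqid = gemmi.SeqId(int(model.resnum[i]), str(model.icode[i]) or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*model.coords[i])
        atom.occ = 1.0
        res.add_atom(atom)
        chains[ch].add_residue(res)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.write_pdb(str(path))


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_curve_table(path: str | Path, axis_kind: str) -> tuple[DenaturationCurve, np.ndarray | None]:
    """Read a denaturation table (CSV or TSV by extension).

    Expected columns: x, signal, optional replicate, optional blank.
    Returns the curve and the per-grid-point blank series if present.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"x", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"curve table {path} missing column(s): {sorted(missing)}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    curve = DenaturationCurve(
        axis_kind=axis_kind,
        x=df["x"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        replicate_id=rep,
    )
    blanks = None
    if "blank" in df.columns:
        grid = df.drop_duplicates("x").sort_values("x")
        blanks = grid["blank"].to_numpy(float)
    return curve, blanks


def write_curve_table(curve: DenaturationCurve, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    curve.to_frame().to_csv(path, sep=sep, index=False)


def profile_to_frame(profile) -> pd.DataFrame:
    """Long-format table of a position profile: position, residue, count,
    frequency and per-column information content in bits."""
    from .consensus import column_information_content

    bits = column_information_content(profile)
    rows = []
    for pos, (cnt, freq) in enumerate(zip(profile.counts, profile.columns), start=1):
        for res in sorted(freq):
            rows.append({
                "position": pos, "residue": res,
                "count": cnt[res], "frequency": freq[res],
                "bits": bits[pos - 1],
            })
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Validated configuration for the pipeline runner.

    Residue ranges are 1-based inclusive throughout (PDB convention).
    """

    out_dir: Path
    seed: int = 0
    structure: Path | None = None
    blade_ranges: tuple[tuple[str, int, int], ...] | None = None
    reference_offsets: tuple[int, int, int, int] | None = None
    repeats_fasta: Path | None = None
    tandem_fasta: Path | None = None
    strand_ranges: tuple[tuple[int, int], ...] | None = None
    n_repeats: int | None = None
    overrides: dict[int, str] = field(default_factory=dict)
    thermal_curve: Path | None = None
    chemical_curve: Path | None = None
    temperature_K: float = 293.15

    _KNOWN = {
        "out_dir", "seed", "structure", "blade_ranges", "reference_offsets",
        "repeats_fasta", "tandem_fasta", "strand_ranges", "n_repeats",
        "overrides", "thermal_curve", "chemical_curve", "temperature_K",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "out_dir" not in d:
            raise ValueError("config requires out_dir")
        d = dict(d)
        for key in ("out_dir", "structure", "repeats_fasta", "tandem_fasta",
                    "thermal_curve", "chemical_curve"):
            if d.get(key) is not None:
                d[key] = Path(d[key])
        if d.get("blade_ranges") is not None:
            d["blade_ranges"] = tuple((str(c), int(s), int(e)) for c, s, e in d["blade_ranges"])
        if d.get("strand_ranges") is not None:
            d["strand_ranges"] = tuple((int(s), int(e)) for s, e in d["strand_ranges"])
        if d.get("reference_offsets") is not None:
            d["reference_offsets"] = tuple(int(o) for o in d["reference_offsets"])
        if d.get("overrides"):
            d["overrides"] = {int(k): str(v) for k, v in d["overrides"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def validate(self) -> None:
        for key in ("structure", "repeats_fasta", "tandem_fasta",
                    "thermal_curve", "chemical_curve"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        if self.blade_ranges is not None:
            BladeSet(ranges=self.blade_ranges)  # reuse its invariant checks
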