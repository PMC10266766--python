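"""Saturation-mutagenesis scanning and solvent-accessibility annotation.

A scan walks every scannable residue of a single chain, featurizes its
masked environment, and predicts the stability change of all 20 possible
amino-acid substitutions (the wild-type "self" row is emitted with
ΔΔG = 0.0 and flagged, so the output is always a complete 20-column
matrix per position).  Burial is annotated from relative solvent
accessibility: per-residue Shrake–Rupley SASA divided by the Sander–Rost
maximum for that residue type, with residues at relative SASA ≥ 0.2
classified exposed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB.DSSP import residue_max_acc
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

from .ddg import Ensemble, build_features, fermi_transform, inverse_fermi
from .representation import RepresentationModel
from .structure import AA_ALPHABET, Structure, residue_sites
from .voxel import featurize_site

logger = logging.getLogger("stabscan.scan")

BURIAL_CUTOFF = 0.2
#: Sander & Rost per-residue maximum accessible surface areas (Å²).
MAX_ACC = residue_max_acc["Sander"]

SCAN_COLUMNS = ["source_id", "chain", "residue_index", "wt_aa", "mut_aa",
                "score_fermi", "ddg_kcal_per_mol", "wt_is_cysteine",
                "self_substitution"]
UNITS_HEADER = "# ddg units: kcal/mol"


class ScanFormatError(ValueError):
    """Malformed scan CSV."""


@dataclass
class ScanTable:
    """Ordered per-variant predictions plus a provenance block (structure
    id, model checksums, grid configuration)."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, ScanTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class BurialAnnotation:
    residue_index: int
    relative_sasa: float | None
    klass: str | None           # "exposed" / "buried" / None when no reference max


def classify_burial(relative_sasa: float, cutoff: float = BURIAL_CUTOFF) -> str:
    """'exposed' iff relative SASA ≥ cutoff (the boundary value itself is
    exposed); negative input is an error."""
    if relative_sasa < 0:
        raise ValueError(f"relative SASA cannot be negative: {relative_sasa}")
    return "exposed" if relative_sasa >= cutoff else "buried"


def _to_biopython(structure: Structure):
    """Build an in-memory Biopython entity from the heavy atoms (SASA is a
    heavy-atom quantity here; hydrogens are skipped)."""
    sb = StructureBuilder()
    sb.init_structure(structure.source_id)
    sb.init_model(0)
    sb.init_chain(structure.chain_id or "A")
    sb.init_seg("    ")
    for res in structure.residues:
        sb.init_residue(res.res_name, " ", res.residue_index, " ")
        for a in res.atoms:
            if a.element == "H":
                continue
            sb.init_atom(a.atom_name, np.asarray(a.coords, dtype=np.float32),
                         0.0, 1.0, " ", a.atom_name.center(4), None,
                         element=a.element or "C")
    return sb.get_structure()


def compute_relative_sasa(structure: Structure,
                          probe_radius: float = 1.4) -> list[BurialAnnotation]:
    """Per-residue relative SASA on the input chain alone.

    Absolute SASA comes from the Shrake–Rupley rolling-probe algorithm
    (probe 1.4 Å) over heavy atoms; each residue's value is divided by the
    Sander–Rost maximum for its type.  Terminal residues can slightly
    exceed 1; values are deliberately not clipped.  Residue types without a
    reference maximum are annotated as missing.
    """
    if not structure.residues:
        return []
    bp = _to_biopython(structure)
    ShrakeRupley(probe_radius=probe_radius).compute(bp, level="R")
    chain = bp[0][structure.chain_id or "A"]
    out: list[BurialAnnotation] = []
    for res in structure.residues:
        key = (" ", res.residue_index, " ")
        sasa = float(chain[key].sasa) if key in chain else 0.0
        max_acc = MAX_ACC.get(res.res_name)
        if max_acc is None:
            logger.warning("residue %s %d: no Sander-Rost reference maximum; "
                           "burial annotation missing", res.res_name,
                           res.residue_index)
            out.append(BurialAnnotation(res.residue_index, None, None))
            continue
        rel = sasa / max_acc
        out.append(BurialAnnotation(res.residue_index, rel, classify_burial(rel)))
    return out


def _checksum(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def saturation_scan(structure: Structure, ensemble: Ensemble,
                    repr_model: RepresentationModel) -> ScanTable:
    """Predict ΔΔG for every site × 20 amino acids.

    Rows are ordered by residue then mutant alphabet; sites skipped by
    ``residue_sites`` (incomplete backbones, non-canonical residues) are
    absent and logged.  The representation model and the ensemble must
    carry the same GridSpec (hard error otherwise), and identical inputs
    and checkpoints always produce a byte-identical table.
    """
    if repr_model.grid_spec != ensemble.grid_spec:
        raise ValueError(
            f"GridSpec mismatch: representation model {repr_model.grid_spec} "
            f"vs ensemble {ensemble.grid_spec}")
    sites = residue_sites(structure)
    if not sites:
        raise ValueError(f"{structure.source_id}: zero scannable sites")
    spec = repr_model.grid_spec
    fermi = ensemble.config.fermi
    freqs = ensemble.frequencies
    self_score = fermi_transform(0.0, fermi)

    rows = []
    for site in sites:
        grid = featurize_site(structure, site, spec)
        emb = repr_model.embed(grid)
        feats = np.stack([build_features(emb, site.wt_aa, mut, freqs)
                          for mut in AA_ALPHABET])
        scores = ensemble.predict_scores(feats)     # (n_models, 20)
        medians = np.median(scores, axis=0)
        for k, mut in enumerate(AA_ALPHABET):
            is_self = mut == site.wt_aa
            rows.append({
                "source_id": structure.source_id,
                "chain": site.chain_id,
                "residue_index": site.residue_index,
                "wt_aa": site.wt_aa,
                "mut_aa": mut,
                "score_fermi": round(self_score if is_self
                                     else float(medians[k]), 6),
                "ddg_kcal_per_mol": 0.0 if is_self
                    else round(float(inverse_fermi(medians[k], fermi)), 4),
                "wt_is_cysteine": site.wt_aa == "C",
                "self_substitution": is_self,
            })
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    provenance = {
        "source_id": structure.source_id,
        "chain": structure.chain_id,
        "n_sites": len(sites),
        "grid_spec": spec.to_dict(),
        "repr_checksum": _checksum(repr_model.net.state()),
        "ensemble_checksum": _checksum(
            a for m in ensemble.models for a in m.net.state()),
    }
    return ScanTable(df=df, provenance=provenance)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_scan_csv(table: ScanTable, path: str | Path) -> None:
    """Serialize a scan: units comment, provenance comment, then CSV with
    ΔΔG at 4 decimals and Fermi scores at 6."""
    df = table.df.copy()
    df["score_fermi"] = df["score_fermi"].map(lambda v: f"{v:.6f}")
    df["ddg_kcal_per_mol"] = df["ddg_kcal_per_mol"].map(lambda v: f"{v:.4f}")
    with open(path, "w", newline="") as f:
        f.write(UNITS_HEADER + "\n")
        f.write("# provenance: " + json.dumps(table.provenance, sort_keys=True)
                + "\n")
        df.to_csv(f, index=False)


def read_scan_csv(path: str | Path) -> ScanTable:
    """Read a scan CSV back; a missing units header is a warning (kcal/mol
    assumed), malformed content raises :class:`ScanFormatError` with the
    offending line number."""
    path = Path(path)
    provenance: dict = {}
    header_lines = 0
    saw_units = False
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            header_lines += 1
            if line.strip() == UNITS_HEADER:
                saw_units = True
            elif line.startswith("# provenance: "):
                try:
                    provenance = json.loads(line[len("# provenance: "):])
                except json.JSONDecodeError:
                    raise ScanFormatError(
                        f"{path}:{header_lines}: unparseable provenance block")
    if not saw_units:
        logger.warning("%s: no units header; assuming ddg in kcal/mol", path)
    try:
        df = pd.read_csv(path, skiprows=header_lines,
                         dtype={"chain": str, "wt_aa": str, "mut_aa": str})
    except Exception as exc:
        raise ScanFormatError(f"{path}: {exc}") from exc
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ScanFormatError(
            f"{path}:{header_lines + 1}: missing columns {missing}")
    for i, (wt, mut) in enumerate(zip(df["wt_aa"], df["mut_aa"])):
        if wt not in AA_ALPHABET or mut not in AA_ALPHABET:
            raise ScanFormatError(
                f"{path}:{header_lines + 2 + i}: non-canonical amino acid "
                f"{wt!r}->{mut!r}")
    df = df[SCAN_COLUMNS]
    return ScanTable(df=df, provenance=provenance)
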