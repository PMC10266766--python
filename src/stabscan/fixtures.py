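"""Seeded generators for toy structures, ΔΔG landscapes and variant tables.

Every other module is testable against these with no external data.  The
structures have ideal backbone internal coordinates (helix φ=−57°, ψ=−47°;
extended φ=ψ=180°), backbone amide hydrogens, and one pseudo side-chain
atom per residue at the Cβ position whose element depends on the residue
type (S for Cys/Met; O for Ser/Thr/Asp/Glu/Asn/Gln/Tyr; N for
Lys/Arg/His/Trp; C otherwise).  Because a residue's own atoms are masked
from its environment, its identity is only visible through its sequence
neighbours; "random" sequences are therefore drawn from a first-order
Markov chain with a high self-transition probability on top of natural
amino-acid frequencies, which puts recoverable wild-type signal into every
masked environment — a stand-in for the statistical regularities real
structural neighbourhoods carry.

The synthetic ΔΔG landscape is a fixed deterministic function of
(wild-type, mutant, burial) plus Gaussian noise, calibrated so values
concentrate in the −1…7 kcal/mol window the Fermi transform focuses on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import (AA_ALPHABET, AA_INDEX, ONE_TO_THREE, AtomRecord,
                        Residue, Structure, write_pdb)

logger = logging.getLogger("stabscan.fixtures")

# -- ideal backbone internal coordinates (Å, degrees) -----------------------
BOND_N_CA, BOND_CA_C, BOND_C_N = 1.458, 1.525, 1.329
BOND_C_O, BOND_N_H = 1.231, 1.010
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA = 111.0, 116.6, 121.7
ANG_CA_C_O, ANG_CA_N_H = 120.5, 119.0
OMEGA = 180.0

PHI_PSI = {"ideal_helix": (-57.0, -47.0), "extended": (180.0, 180.0)}

#: Pseudo side-chain element by residue type (identity-correlated, so the
#: classification task has signal at toy scale).
SIDECHAIN_ELEMENT = {
    **{aa: "S" for aa in "CM"},
    **{aa: "O" for aa in "STDENQY"},
    **{aa: "N" for aa in "KRHW"},
    **{aa: "C" for aa in "AVLIPFG"},
}

#: Approximate natural amino-acid frequencies (vertebrate proteomes),
#: alphabetical one-letter order; used by the "random" sequence sampler.
NATURAL_FREQS = np.array([
    0.083, 0.018, 0.059, 0.063, 0.039, 0.071, 0.023, 0.057, 0.058, 0.100,
    0.024, 0.044, 0.048, 0.037, 0.051, 0.066, 0.053, 0.069, 0.013, 0.034,
])
NATURAL_FREQS = NATURAL_FREQS / NATURAL_FREQS.sum()

#: Markov self-transition probability of the "random" sequence sampler.
SEQ_SELF_TRANSITION = 0.75

# -- fixed tables of the synthetic ΔΔG rule ---------------------------------
#: Kyte–Doolittle hydropathy rescaled to [0, 1], alphabetical order.
_KD = np.array([1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
                1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3])
DDG_PROPENSITY = (_KD + 4.5) / 9.0                       # q(aa) in [0, 1]
DDG_WT_SCALE = 0.6 + 0.8 * np.arange(20) / 19.0          # s(aa) in [0.6, 1.4]
#: d(wt, mut) substitution table, rows wt / columns mut.
DDG_SUB_TABLE = (1.2 + 2.6 * DDG_PROPENSITY[None, :]
                 - 1.4 * DDG_PROPENSITY[:, None])
DDG_BURIAL_BOOST = 0.6                                   # b: ×(1+b) when buried


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy structure."""

    n_residues: int = 30
    geometry: str = "ideal_helix"    # ideal_helix | extended | compact_bundle
    sequence: str = "random"
    noise_sd: float = 0.2            # kcal/mol, for the ΔΔG generator
    seed: int = 0
    n_helices: int = 7               # compact_bundle only (1 core + ring)

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.geometry not in ("ideal_helix", "extended", "compact_bundle"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF placement: the point at distance ``bond`` from c, with angle
    b-c-new and dihedral a-b-c-new."""
    theta, chi = np.radians(angle_deg), np.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(theta), np.cos(chi) * np.sin(theta),
                         np.sin(chi) * np.sin(theta)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n, ca, c):
    """Ideal Cβ from the backbone (standard linear combination)."""
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict]:
    """N/CA/C/O (+amide H from residue 2 on) coordinates for one chain."""
    ang = np.radians(ANG_N_CA_C)
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(n_res - 1):
        N.append(_place(N[i], CA[i], C[i], BOND_C_N, ANG_CA_C_N, psi))
        CA.append(_place(CA[i], C[i], N[i + 1], BOND_N_CA, ANG_C_N_CA, OMEGA))
        C.append(_place(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANG_N_CA_C, phi))
    out = []
    for i in range(n_res):
        atoms = {"N": N[i], "CA": CA[i], "C": C[i]}
        if i + 1 < n_res:
            atoms["O"] = _place(N[i + 1], CA[i], C[i], BOND_C_O, ANG_CA_C_O, 180.0)
        else:
            atoms["O"] = _place(N[i], CA[i], C[i], BOND_C_O, ANG_CA_C_O,
                                psi + 180.0)
        if i > 0:
            atoms["H"] = _place(C[i - 1], CA[i], N[i], BOND_N_H,
                                ANG_CA_N_H, 180.0)
        out.append(atoms)
    return out


def _sample_sequence(n: int, rng: np.random.Generator) -> str:
    """Markov sequence: self-transition 0.75, otherwise natural frequencies."""
    seq = [AA_ALPHABET[rng.choice(20, p=NATURAL_FREQS)]]
    for _ in range(n - 1):
        if rng.random() < SEQ_SELF_TRANSITION:
            seq.append(seq[-1])
        else:
            seq.append(AA_ALPHABET[rng.choice(20, p=NATURAL_FREQS)])
    return "".join(seq)


def _axis_align(coords: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Rotate so the principal axis of the CA trace lies along +z, centroid
    at the origin."""
    center = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(axis @ z)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return (coords - center) @ rot.T


def _residues_from_atoms(seq: str, per_res_atoms: list[dict],
                         start_index: int = 1, chain: str = "A"
                         ) -> list[Residue]:
    residues = []
    for i, (aa, atoms) in enumerate(zip(seq, per_res_atoms)):
        idx = start_index + i
        res = Residue(chain_id=chain, residue_index=idx,
                      res_name=ONE_TO_THREE[aa])
        order = ["N", "CA", "C", "O", "H"]
        for name in order:
            if name in atoms:
                element = "C" if name in ("CA", "C") else name[0]
                res.atoms.append(AtomRecord(atom_name=name, element=element,
                                            coords=np.asarray(atoms[name]),
                                            residue_index=idx, chain_id=chain))
        cb = _cb_position(atoms["N"], atoms["CA"], atoms["C"])
        element = SIDECHAIN_ELEMENT[aa]
        name = "SG" if aa == "C" else "CB"
        res.atoms.append(AtomRecord(atom_name=name, element=element,
                                    coords=cb, residue_index=idx,
                                    chain_id=chain))
        residues.append(res)
    return residues


def make_toy_structure(spec: FixtureSpec,
                       pdb_path: str | Path | None = None) -> Structure:
    """Build a toy structure per the spec; optionally write it as PDB.

    ``compact_bundle`` packs ``n_helices`` axis-aligned helices (one
    central, the rest on a surrounding ring, alternating direction) tightly
    enough that core sites fall below the 0.2 relative-SASA burial cutoff.
    Pure function of (spec): the same spec yields identical coordinates and
    identical PDB bytes.
    """
    rng = np.random.default_rng(spec.seed)
    seq = (spec.sequence if spec.sequence != "random"
           else _sample_sequence(spec.n_residues, rng))
    if len(seq) != spec.n_residues:
        raise ValueError("sequence length does not match n_residues")
    if any(aa not in AA_INDEX for aa in seq):
        raise ValueError("sequence contains non-canonical letters")

    structure = Structure(source_id=f"toy_{spec.geometry}_{spec.seed}",
                          chain_id="A")
    if spec.geometry in PHI_PSI:
        phi, psi = PHI_PSI[spec.geometry]
        atoms = _build_backbone(spec.n_residues, phi, psi)
        structure.residues = _residues_from_atoms(seq, atoms)
        if pdb_path is not None:
            write_pdb(structure, pdb_path)
        return structure

    # compact_bundle: one core helix plus a ring
    k = spec.n_helices
    if k < 3:
        raise ValueError("compact_bundle needs at least 3 helices")
    lengths = [spec.n_residues // k + (1 if i < spec.n_residues % k else 0)
               for i in range(k)]
    if min(lengths) < 3:
        raise ValueError("too few residues per helix for a bundle")
    phi, psi = PHI_PSI["ideal_helix"]
    ring_radius = 6.3
    start = 1
    pos = 0
    for h, n_res in enumerate(lengths):
        atoms = _build_backbone(n_res, phi, psi)
        names = [list(a.keys()) for a in atoms]
        flat = np.array([xyz for a in atoms for xyz in a.values()])
        ca = np.array([a["CA"] for a in atoms])
        flat = _axis_align(flat, ca)
        if h % 2 == 1:                      # antiparallel packing
            flat = flat @ np.diag([1.0, -1.0, -1.0])
        if h == 0:
            offset = np.zeros(3)
        else:
            angle = 2.0 * np.pi * (h - 1) / (k - 1)
            offset = ring_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        flat = flat + offset
        i = 0
        rebuilt = []
        for res_names in names:
            d = {}
            for name in res_names:
                d[name] = flat[i]
                i += 1
            rebuilt.append(d)
        structure.residues.extend(_residues_from_atoms(
            seq[pos:pos + n_res], rebuilt, start_index=start))
        start += n_res + 5                  # numbering gap between segments
        pos += n_res
    if pdb_path is not None:
        write_pdb(structure, pdb_path)
    return structure


def make_disulfide_pair_structure(seed: int = 0) -> Structure:
    """Two short extended segments whose central cysteines form an SG–SG
    contact at 2.05 Å (a cystine), plus surrounding non-cysteine residues.
    Used to exercise the disulfide training filter."""
    spec1 = FixtureSpec(n_residues=5, geometry="extended", sequence="AACAA",
                        seed=seed)
    s1 = make_toy_structure(spec1)
    s2 = make_toy_structure(spec1)
    sg1 = next(r for r in s1.residues if r.res_name == "CYS").atom("SG").coords
    sg2 = next(r for r in s2.residues if r.res_name == "CYS").atom("SG").coords
    # flip the second strand and translate so the SG atoms sit 2.05 Å apart
    flip = np.diag([1.0, -1.0, 1.0])
    shift = sg1 + np.array([0.0, 2.05, 0.0]) - flip @ sg2
    for res in s2.residues:
        res.residue_index += 10
        for a in res.atoms:
            a.coords = flip @ a.coords + shift
            a.residue_index = res.residue_index
    s1.residues.extend(s2.residues)
    s1.source_id = f"toy_cystine_{seed}"
    return s1


# ---------------------------------------------------------------------------
# Synthetic ΔΔG landscape
# ---------------------------------------------------------------------------

def true_ddg(wt_aa: str, mut_aa: str, buried: bool) -> float:
    """The noiseless synthetic rule:
    ΔΔG = s(wt) · d(wt, mut) · (1 + b·buried), self-substitutions 0 exactly."""
    if wt_aa == mut_aa:
        return 0.0
    i, j = AA_INDEX[wt_aa], AA_INDEX[mut_aa]
    return float(DDG_WT_SCALE[i] * DDG_SUB_TABLE[i, j]
                 * (1.0 + DDG_BURIAL_BOOST * buried))


def make_synthetic_ddg(structure: Structure, seed: int = 0,
                       noise_sd: float = 0.2,
                       burial: dict[int, bool] | None = None) -> pd.DataFrame:
    """Saturation training table: the 19 substitutions of every scannable
    residue, ΔΔG = true rule + N(0, noise_sd).

    ``burial`` maps residue_index → buried flag; when omitted it is computed
    from relative SASA at the 0.2 cutoff.  Columns: source_id, chain,
    residue_index, wt_aa, mut_aa, ddg_kcal_per_mol, plus the noiseless
    ddg_true for evaluation.  Deterministic given the seed.
    """
    from .scan import compute_relative_sasa  # deferred: scan imports ddg
    from .structure import residue_sites

    if burial is None:
        burial = {ann.residue_index: ann.klass == "buried"
                  for ann in compute_relative_sasa(structure)
                  if ann.klass is not None}
    rng = np.random.default_rng(seed)
    rows = []
    for site in residue_sites(structure):
        if site.residue_index not in burial:
            raise ValueError(f"residue {site.residue_index} lacks a burial "
                             "annotation")
        b = burial[site.residue_index]
        for mut in AA_ALPHABET:
            if mut == site.wt_aa:
                continue
            g = true_ddg(site.wt_aa, mut, b)
            rows.append({"source_id": structure.source_id, "chain": site.chain_id,
                         "residue_index": site.residue_index,
                         "wt_aa": site.wt_aa, "mut_aa": mut,
                         "ddg_kcal_per_mol": g + rng.normal(0.0, noise_sd),
                         "ddg_true": g})
    return pd.DataFrame(rows)


def make_variant_table(ddg_table: pd.DataFrame, seed: int = 0,
                       n_variants: int | None = None,
                       decoy_rate: float = 0.1) -> pd.DataFrame:
    """Sample a population/clinical variant table from a ΔΔG table.

    Pathogenic labels are drawn with probability increasing in the true
    ΔΔG (logistic around 1.5 kcal/mol); allele frequencies are log-uniform
    in [1e-6, 1e-1].  A ``decoy_rate`` fraction of rows get a wrong
    wild-type letter, to exercise join rejection downstream.  Columns:
    protein_id, residue_index, wt_aa, mut_aa, class, allele_frequency.
    """
    if ddg_table.empty:
        raise ValueError("ddg_table is empty")
    rng = np.random.default_rng(seed)
    n = n_variants or min(200, len(ddg_table))
    picks = rng.choice(len(ddg_table), size=n, replace=False)
    sub = ddg_table.iloc[picks].reset_index(drop=True)
    ddg = sub.get("ddg_true", sub["ddg_kcal_per_mol"]).to_numpy(dtype=float)
    p_path = 1.0 / (1.0 + np.exp(-1.6 * (ddg - 1.5)))
    klass = np.where(rng.random(n) < p_path, "pathogenic", "benign")
    af = 10.0 ** rng.uniform(-6.0, -1.0, size=n)
    wt = sub["wt_aa"].to_numpy(dtype=object)
    decoy = rng.random(n) < decoy_rate
    for i in np.flatnonzero(decoy):
        others = [a for a in AA_ALPHABET if a != wt[i]]
        wt[i] = others[rng.integers(len(others))]
    return pd.DataFrame({
        "protein_id": sub["source_id"], "residue_index": sub["residue_index"],
        "wt_aa": wt, "mut_aa": sub["mut_aa"], "class": klass,
        "allele_frequency": af,
    })


def write_fixture_set(out_dir: str | Path, n_proteins: int = 4,
                      n_residues: int = 30, geometry: str = "ideal_helix",
                      noise_sd: float = 0.2, seed: int = 0) -> dict:
    """Write a directory of PDBs + training CSV + variant TSV + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "geometry": geometry, "noise_sd": noise_sd,
                "proteins": []}
    tables = []
    for i in range(n_proteins):
        spec = FixtureSpec(n_residues=n_residues, geometry=geometry,
                           noise_sd=noise_sd, seed=seed + i)
        st = make_toy_structure(spec)
        pdb = out_dir / f"{st.source_id}.pdb"
        write_pdb(st, pdb)
        tables.append(make_synthetic_ddg(st, seed=seed + i, noise_sd=noise_sd))
        manifest["proteins"].append({"source_id": st.source_id,
                                     "pdb": pdb.name, "seed": seed + i,
                                     "n_residues": n_residues})
    ddg = pd.concat(tables, ignore_index=True)
    ddg.to_csv(out_dir / "training_ddg.csv", index=False)
    variants = make_variant_table(ddg, seed=seed)
    variants.to_csv(out_dir / "variants.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
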