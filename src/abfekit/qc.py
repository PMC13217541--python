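"""Structure quality control and triage for protein–ligand complexes.

Before any energetics, every complex passes a structure interface that
either converts it for simulation, rejects it for a scientific reason
(membrane protein, unsupported chemistry, irreparable structural flaws) or
fails technically (an internal check crashed).  Exactly one category is
assigned per complex, with a fixed priority order so ties break
deterministically.  Non-fatal findings (changed disulfide count, detected
chain gaps, skipped residue templates) become notes on a still-converted
complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .structio import MolecularSystem, ParameterSet
from .valstats import round_half_away

__all__ = [
    "TriageCategory",
    "TriageReport",
    "classify_complex",
    "check_site_completeness",
    "check_sequence_consistency",
    "detect_chain_gaps",
    "detect_disulfides",
    "compare_disulfides",
    "triage",
    "summarize_triage",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

WATER_NAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3"}

#: Monatomic ions with routinely shipped force-field parameters.
SUPPORTED_METALS = {"NA", "K", "MG", "CA", "CL", "ZN"}

_SIDECHAINS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

#: Expected heavy-atom names per standard amino acid (backbone + side chain).
AA_HEAVY_ATOMS = {res: frozenset(["N", "CA", "C", "O"] + side)
                  for res, side in _SIDECHAINS.items()}

REJECTION_REASONS = (
    "membrane-protein", "nonstandard-amino-acid", "unsupported-metal",
    "unsupported-cosolvent", "missing-atoms-near-site",
    "sequence-structure-mismatch", "unknown-sequence",
    "ligand-parameterization-failure", "peptide-ligand-missing-atoms",
)
TECHNICAL_REASONS = ("gap-detection-failure", "other-technical")


class GapDetectionError(RuntimeError):
    """Gap detection could not run (e.g. missing backbone atoms)."""


@dataclass
class TriageCategory:
    outcome: str  # converted | rejected-scientific | failed-technical
    reason: str = "none"

    def __post_init__(self):
        if (self.reason == "none") != (self.outcome == "converted"):
            raise ValueError("reason must be 'none' iff outcome is 'converted'")


@dataclass
class TriageReport:
    complex_id: str
    category: TriageCategory
    evidence: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.category.outcome != "converted" and not self.evidence:
            raise ValueError("non-converted reports require evidence")

    def as_dict(self) -> dict:
        return {
            "complex_id": self.complex_id,
            "outcome": self.category.outcome,
            "reason": self.category.reason,
            "evidence": list(self.evidence),
            "notes": list(self.notes),
        }


def _residue_groups(system: MolecularSystem):
    """Atoms grouped by (chain, resid, resname) in file order."""
    groups: dict[tuple, list[int]] = {}
    for i, a in enumerate(system.atoms):
        groups.setdefault((a.chain, a.resid, a.resname), []).append(i)
    return groups


def classify_complex(system: MolecularSystem,
                     supported_metals: set[str] = SUPPORTED_METALS,
                     standard_residues: set[str] = STANDARD_RESIDUES
                     ) -> tuple[TriageCategory, list[str]]:
    """First-stage scope classification.

    Fixed priority: membrane protein → nonstandard amino acid → unsupported
    metal → unsupported cosolvent; otherwise provisionally converted.
    Returns the category plus supporting evidence strings.
    """
    findings: dict[str, list[str]] = {r: [] for r in REJECTION_REASONS[:4]}
    if str(system.metadata.get("membrane", "")).lower() in ("true", "1", "yes"):
        findings["membrane-protein"].append("metadata flags a membrane protein")

    ligand = set(int(i) for i in system.ligand_selection)
    for (chain, resid, resname), idx in _residue_groups(system).items():
        if set(idx) & ligand or resname in WATER_NAMES:
            continue
        atoms = [system.atoms[i] for i in idx]
        hetero = all(a.record_kind == "hetero" for a in atoms)
        if hetero and len(atoms) == 1:
            elem = atoms[0].element.upper()
            if elem not in supported_metals:
                findings["unsupported-metal"].append(
                    f"monatomic hetero species {resname} {chain}{resid} "
                    f"(element {elem}) has no shipped parameters")
        elif hetero:
            findings["unsupported-cosolvent"].append(
                f"polyatomic hetero residue {resname} {chain}{resid} "
                "outside the ligand selection")
        elif resname not in standard_residues:
            findings["nonstandard-amino-acid"].append(
                f"residue {resname} {chain}{resid} is not a standard amino acid")

    for reason in REJECTION_REASONS[:4]:
        if findings[reason]:
            return TriageCategory("rejected-scientific", reason), findings[reason]
    return TriageCategory("converted"), []


def check_site_completeness(system: MolecularSystem,
                            templates: dict | None = None,
                            site_radius_A: float = 3.0
                            ) -> tuple[list[tuple], list[str]]:
    """Missing heavy atoms in residues lining the ligand binding site.

    Only residues with at least one atom within ``site_radius_A`` of any
    ligand atom are checked against their heavy-atom template.  Residues
    without a template are skipped with a note.  Returns
    (violations as ((chain, resid, resname), missing_atom_name), notes).
    """
    if system.ligand_selection.size == 0:
        raise ValueError("ligand selection must be non-empty")
    templates = templates if templates is not None else AA_HEAVY_ATOMS
    lig_coords = system.coords[system.ligand_selection]
    ligand = set(int(i) for i in system.ligand_selection)
    violations: list[tuple] = []
    notes: list[str] = []
    for key, idx in _residue_groups(system).items():
        if set(idx) & ligand:
            continue
        resname = key[2]
        res_coords = np.array([system.atoms[i].coords for i in idx])
        d2 = np.min(np.sum(
            (res_coords[:, None, :] - lig_coords[None, :, :]) ** 2, axis=2))
        if d2 > site_radius_A ** 2:
            continue
        if resname not in templates:
            if resname not in WATER_NAMES:
                notes.append(f"no heavy-atom template for {resname} "
                             f"{key[0]}{key[1]}; skipped")
            continue
        present = {system.atoms[i].name for i in idx
                   if system.atoms[i].element.upper() != "H"}
        for missing in sorted(set(templates[resname]) - present):
            violations.append((key, missing))
    return violations, notes


def _structure_sequences(system: MolecularSystem) -> dict[str, list[tuple[int, str]]]:
    """Per-chain (resid, one-letter) lists of resolved standard residues."""
    chains: dict[str, list[tuple[int, str]]] = {}
    seen = set()
    for a in system.atoms:
        if a.record_kind != "standard-residue":
            continue
        key = (a.chain, a.resid)
        if key in seen or a.resname not in THREE_TO_ONE:
            continue
        seen.add(key)
        chains.setdefault(a.chain, []).append((a.resid, THREE_TO_ONE[a.resname]))
    return chains


def check_sequence_consistency(system: MolecularSystem,
                               sequences: dict[str, str]
                               ) -> tuple[str, list[str]]:
    """Compare per-chain structure residues against reference sequences.

    Global alignment (match +1, mismatch −1, gap −2).  'mismatch' when any
    aligned resolved residue differs from the reference; 'unknown-sequence'
    when the reference carries 'X' at a resolved position or a chain has no
    record at all.
    """
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2

    status = "ok"
    details: list[str] = []
    for chain, residues in _structure_sequences(system).items():
        if chain not in sequences:
            return "unknown-sequence", [f"chain {chain} has no sequence record"]
        struct_seq = "".join(letter for _, letter in residues)
        ref_seq = sequences[chain]
        alignment = aligner.align(struct_seq, ref_seq)[0]
        for (s_start, s_end), (r_start, r_end) in zip(*alignment.aligned):
            for off in range(s_end - s_start):
                s_letter = struct_seq[s_start + off]
                r_letter = ref_seq[r_start + off]
                resid = residues[s_start + off][0]
                if r_letter == "X":
                    return "unknown-sequence", [
                        f"chain {chain} residue {resid}: reference sequence "
                        "unknown ('X') at a resolved position"]
                if s_letter != r_letter:
                    status = "mismatch"
                    details.append(
                        f"chain {chain} residue {resid}: structure {s_letter} "
                        f"vs sequence {r_letter}")
    return status, details


def detect_chain_gaps(system: MolecularSystem,
                      max_CN_dist_A: float = 2.5) -> list[tuple[str, int, int]]:
    """Backbone-continuity gaps between consecutive residues of each chain.

    A gap is flagged when the C(i)–N(i+1) distance exceeds the threshold or
    residue numbering jumps by more than one without covalent continuity.
    Raises :class:`GapDetectionError` when a polymer residue lacks its C or
    N backbone atom.
    """
    backbone: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    for a in system.atoms:
        if a.record_kind != "standard-residue":
            continue
        if a.name in ("N", "C"):
            backbone.setdefault(a.chain, {}).setdefault(a.resid, {})[a.name] = a.coords
    gaps: list[tuple[str, int, int]] = []
    for chain, residues in backbone.items():
        resids = sorted(residues)
        if len(resids) < 2:
            continue
        for r1, r2 in zip(resids[:-1], resids[1:]):
            if "C" not in residues[r1] or "N" not in residues[r2]:
                raise GapDetectionError(
                    f"chain {chain}: backbone atoms missing around residues "
                    f"{r1}-{r2}")
            dist = float(np.linalg.norm(residues[r1]["C"] - residues[r2]["N"]))
            if dist > max_CN_dist_A or r2 - r1 > 1:
                gaps.append((chain, r1, r2))
    return gaps


def detect_disulfides(system: MolecularSystem,
                      ss_cutoff_A: float = 2.1) -> list[tuple[tuple, tuple]]:
    """Geometric SG–SG pairs within the cutoff, greedy nearest-first.

    Each SG participates in at most one pair.  Pairs are returned as
    ((chain, resid), (chain, resid)) tuples, sorted for determinism.
    """
    sg = [(a.chain, a.resid, a.coords) for a in system.atoms
          if a.name == "SG" and a.resname == "CYS"]
    candidates = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = float(np.linalg.norm(sg[i][2] - sg[j][2]))
            if d <= ss_cutoff_A:
                candidates.append((d, i, j))
    candidates.sort()
    used: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(tuple(sorted([(sg[i][0], sg[i][1]), (sg[j][0], sg[j][1])])))
    return sorted(pairs)


def compare_disulfides(before: list, after: list) -> tuple[str, list]:
    """'preserved' when the two pair sets agree, else 'changed' with the
    symmetric difference."""
    b = {tuple(sorted(p)) for p in before}
    a = {tuple(sorted(p)) for p in after}
    changed = sorted(b.symmetric_difference(a))
    return ("preserved", []) if not changed else ("changed", changed)


def triage(system: MolecularSystem, params: ParameterSet | None = None,
           sequences: dict[str, str] | None = None,
           complex_id: str = "complex",
           supported_metals: set[str] = SUPPORTED_METALS,
           site_radius_A: float = 3.0,
           ss_cutoff_A: float = 2.1,
           max_CN_dist_A: float = 2.5) -> TriageReport:
    """Full per-complex triage: classification, site completeness, sequence
    consistency, gap detection and disulfide comparison in fixed order.

    The first fatal finding sets the category; any check that raises an
    internal error maps to a technical failure named after the stage.
    Detected gaps and changed disulfide counts are non-fatal notes (gap
    repair is out of scope; disulfide changes were observed not to alter
    binding estimates for stable proteins).
    """
    notes = list(system.metadata.get("notes", []))

    category, evidence = classify_complex(system, supported_metals)
    if category.outcome != "converted":
        return TriageReport(complex_id, category, evidence, notes)

    # ligand parameterization (when a parameter set accompanies the complex)
    if params is not None:
        try:
            params.check_compatible(system)
        except Exception as exc:
            return TriageReport(
                complex_id,
                TriageCategory("rejected-scientific",
                               "ligand-parameterization-failure"),
                [f"parameter assignment failed: {exc}"], notes)

    # binding-site completeness (protein residues, then peptide ligands)
    try:
        violations, site_notes = check_site_completeness(
            system, site_radius_A=site_radius_A)
        notes.extend(site_notes)
    except Exception as exc:
        return TriageReport(
            complex_id, TriageCategory("failed-technical", "other-technical"),
            [f"site-completeness check crashed: {exc}"], notes)
    if violations:
        evidence = [
            f"residue {resname} {chain}{resid} is missing heavy atom "
            f"{name} within {site_radius_A} Å of the ligand"
            for (chain, resid, resname), name in violations]
        return TriageReport(
            complex_id,
            TriageCategory("rejected-scientific", "missing-atoms-near-site"),
            evidence, notes)

    lig_res = {system.atoms[int(i)].resname for i in system.ligand_selection}
    if lig_res and lig_res <= STANDARD_RESIDUES:
        # peptide ligand: its residues must be complete, too
        missing = []
        groups = _residue_groups(system)
        lig = set(int(i) for i in system.ligand_selection)
        for (chain, resid, resname), idx in groups.items():
            if not set(idx) & lig or resname not in AA_HEAVY_ATOMS:
                continue
            present = {system.atoms[i].name for i in idx
                       if system.atoms[i].element.upper() != "H"}
            missing += [f"peptide-ligand residue {resname} {chain}{resid} "
                        f"is missing heavy atom {m}"
                        for m in sorted(set(AA_HEAVY_ATOMS[resname]) - present)]
        if missing:
            return TriageReport(
                complex_id,
                TriageCategory("rejected-scientific",
                               "peptide-ligand-missing-atoms"),
                missing, notes)

    if sequences is not None:
        try:
            status, details = check_sequence_consistency(system, sequences)
        except Exception as exc:
            return TriageReport(
                complex_id,
                TriageCategory("failed-technical", "other-technical"),
                [f"sequence-consistency check crashed: {exc}"], notes)
        if status == "mismatch":
            return TriageReport(
                complex_id,
                TriageCategory("rejected-scientific",
                               "sequence-structure-mismatch"), details, notes)
        if status == "unknown-sequence":
            return TriageReport(
                complex_id,
                TriageCategory("rejected-scientific", "unknown-sequence"),
                details, notes)

    try:
        gaps = detect_chain_gaps(system, max_CN_dist_A)
    except Exception as exc:
        return TriageReport(
            complex_id, TriageCategory("failed-technical",
                                       "gap-detection-failure"),
            [f"gap detection suffered a fatal error: {exc}"], notes)
    notes += [f"chain gap between {chain}{r1} and {chain}{r2} "
              "(repair out of scope)" for chain, r1, r2 in gaps]

    try:
        geometric = detect_disulfides(system, ss_cutoff_A)
        declared = [tuple(sorted(p)) for p in system.metadata.get("ssbond", [])]
        status, changed = compare_disulfides(declared, geometric)
    except Exception as exc:
        return TriageReport(
            complex_id, TriageCategory("failed-technical", "other-technical"),
            [f"disulfide comparison crashed: {exc}"], notes)
    if status == "changed":
        notes.append(
            f"disulfide count changed by the interface ({len(changed)} pair(s) "
            "differ); converted with a note")

    return TriageReport(complex_id, TriageCategory("converted"), [], notes)


def summarize_triage(reports: list[TriageReport]) -> pd.DataFrame:
    """Counts and percentages per outcome and, within each outcome group,
    per reason (one-decimal, half-away-from-zero rounding).
    """
    if not reports:
        raise ValueError("at least one triage report is required")
    total = len(reports)
    rows = []
    outcomes = ["converted", "rejected-scientific", "failed-technical"]
    by_outcome = {o: [r for r in reports if r.category.outcome == o]
                  for o in outcomes}
    for outcome in outcomes:
        group = by_outcome[outcome]
        rows.append({"group": "outcome", "key": outcome, "count": len(group),
                     "percent": round_half_away(100.0 * len(group) / total, 1)})
    for outcome in ("rejected-scientific", "failed-technical"):
        group = by_outcome[outcome]
        if not group:
            continue
        reasons = sorted({r.category.reason for r in group})
        for reason in reasons:
            cnt = sum(1 for r in group if r.category.reason == reason)
            rows.append({
                "group": outcome, "key": reason, "count": cnt,
                "percent": round_half_away(100.0 * cnt / len(group), 1)})
    return pd.DataFrame(rows, columns=["group", "key", "count", "percent"])
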