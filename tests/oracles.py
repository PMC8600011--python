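"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (nested loops, direct
formulas) and deliberately shares no code path with the package modules
it checks.
"""

from __future__ import annotations

import math

import numpy as np

from nabind.pharmacophore import ALL_CLASSES


def brute_signature(positions, labels, cutoffs):
    """O(n^2 * pairs * bins) cumulative pair counter.

    Returns {(class_a, class_b, cutoff): count} over unordered class
    pairs (canonical order) for unordered atom pairs.
    """
    pairs = []
    for i, a in enumerate(ALL_CLASSES):
        for b in ALL_CLASSES[i:]:
            pairs.append((a, b))
    counts = {(a, b, d): 0 for a, b in pairs for d in cutoffs}
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            dist = math.dist(positions[i], positions[j])
            for a, b in pairs:
                hit = ((a in labels[i] and b in labels[j])
                       or (b in labels[i] and a in labels[j]))
                if not hit:
                    continue
                for d in cutoffs:
                    if dist <= d:
                        counts[(a, b, d)] += 1
    return counts


def brute_environment(structure, site_key, radius):
    """All-pairs residue-environment scan (indices into structure.atoms)."""
    site = [a for a in structure.atoms if a.residue_key == site_key]
    out = []
    for i, a in enumerate(structure.atoms):
        for s in site:
            if math.dist(a.position, s.position) <= radius:
                out.append(i)
                break
    return out


# --- interaction classifier -------------------------------------------------

_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "F": 1.47,
        "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "MG": 1.73,
        "ZN": 1.39, "CA": 2.31, "NA": 2.27, "K": 2.75, "MN": 1.97,
        "FE": 1.94, "CU": 1.40, "NI": 1.63, "CO": 1.95, "CD": 1.58}
_COV = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "F": 0.57,
        "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20, "MG": 1.41,
        "ZN": 1.22, "CA": 1.76, "NA": 1.66, "K": 2.03, "MN": 1.39,
        "FE": 1.32, "CU": 1.32, "NI": 1.24, "CO": 1.26, "CD": 1.44}
_METALS = {"MG", "ZN", "CA", "NA", "K", "MN", "FE", "CU", "NI", "CO", "CD"}
_RINGS_PROT = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}
_PURINES = {"DA", "DG", "A", "G", "DI", "I"}
_NUC = {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I"}
_CARBONYL_O = {"O", "OXT", "OD1", "OE1", "O2", "O4", "O6"}
_CARBONYL_C = {"C", "CG", "CD", "C2", "C4", "C6"}


def _props(atom, labels, is_nucleic):
    el = atom.element.upper()
    p = {}
    if is_nucleic:
        p["donor"] = el in ("N", "O")
        p["acceptor"] = el in ("N", "O")
        p["negative"] = atom.name in ("OP1", "OP2", "OP3", "O1P", "O2P", "O3P")
        p["positive"] = False
        p["hydrophobic"] = False
    else:
        p["donor"] = "donor" in labels
        p["acceptor"] = "acceptor" in labels
        p["positive"] = "positive" in labels
        p["negative"] = "negative" in labels
        p["hydrophobic"] = "hydrophobic" in labels and el == "C"
    return p


def brute_interaction_counts(structure, labels, scope="inter"):
    """Independent all-pairs re-derivation of the 13 contact-type counts."""
    from nabind.interactions import INTERACTION_TYPES

    atoms = structure.atoms
    nuc_chains = set(structure.nucleic_chains())
    prot_chains = set(structure.protein_chains())
    props = [_props(a, labels[i], a.chain_id in nuc_chains)
             for i, a in enumerate(atoms)]
    # covalent neighbours within the same residue
    neigh = {i: [] for i in range(len(atoms))}
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if atoms[i].residue_key != atoms[j].residue_key:
                continue
            d = math.dist(atoms[i].position, atoms[j].position)
            if d <= _COV.get(atoms[i].element.upper(), 1.0) + \
                    _COV.get(atoms[j].element.upper(), 1.0) + 0.4:
                neigh[i].append(j)
                neigh[j].append(i)

    def angle(p1, v, p2):
        a = np.asarray(p1) - np.asarray(v)
        b = np.asarray(p2) - np.asarray(v)
        c = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    def donor_ok(i, j):
        if not neigh[i]:
            return True
        return any(angle(atoms[n].position, atoms[i].position,
                         atoms[j].position) >= 90.0 for n in neigh[i])

    counts = {t: 0 for t in INTERACTION_TYPES}
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ai, aj = atoms[i], atoms[j]
            if ai.residue_key == aj.residue_key:
                continue
            if scope == "inter":
                ok = (ai.chain_id in prot_chains and aj.chain_id in nuc_chains) \
                    or (aj.chain_id in prot_chains and ai.chain_id in nuc_chains)
                if not ok:
                    continue
            d = math.dist(ai.position, aj.position)
            if d > 5.5:
                continue
            pi, pj = props[i], props[j]
            eli, elj = ai.element.upper(), aj.element.upper()
            vdw_sum = _VDW.get(eli, 1.8) + _VDW.get(elj, 1.8)
            matched = []
            if d <= _COV.get(eli, 1.0) + _COV.get(elj, 1.0) + 0.4:
                matched.append("covalent")
            if d < vdw_sum - 0.5:
                matched.append("clash")
            elif d < vdw_sum:
                matched.append("vdw_clash")
            elif d <= vdw_sum + 0.5:
                matched.append("vdw")
            if d <= 3.5 and ((pi["donor"] and pj["acceptor"] and donor_ok(i, j))
                             or (pj["donor"] and pi["acceptor"]
                                 and donor_ok(j, i))):
                matched.append("hbond")
            if d <= 3.8 and ((eli == "C" and pj["acceptor"])
                             or (elj == "C" and pi["acceptor"])):
                matched.append("weak_hbond")
            if d <= 4.0 and ((pi["positive"] and pj["negative"])
                             or (pj["positive"] and pi["negative"])):
                matched.append("ionic")
            if d <= 4.5 and pi["hydrophobic"] and pj["hydrophobic"]:
                matched.append("hydrophobic")
            if d <= 3.6 and (
                    (ai.name in _CARBONYL_O and aj.name in _CARBONYL_C
                     and elj == "C")
                    or (aj.name in _CARBONYL_O and ai.name in _CARBONYL_C
                        and eli == "C")):
                matched.append("carbonyl")
            if d <= 3.5 and ((eli in ("CL", "BR", "I") and pj["acceptor"])
                             or (elj in ("CL", "BR", "I") and pi["acceptor"])):
                matched.append("halogen_bond")
            if d <= 2.8 and ((eli in _METALS and elj in ("O", "N", "S"))
                             or (elj in _METALS and eli in ("O", "N", "S"))):
                matched.append("metal")
            if not matched and d <= 5.0:
                matched.append("proximal")
            for t in matched:
                counts[t] += 1
    # aromatic ring-centroid contacts
    rings = []
    for key, atom_list in structure.residues():
        resname = atom_list[0].residue_name
        names = {a.name: a for a in atom_list}
        if resname in _RINGS_PROT:
            defs, cls = _RINGS_PROT[resname], "protein"
        elif resname in _NUC:
            defs = ([("N9", "C8", "N7", "C5", "C4"),
                     ("N1", "C2", "N3", "C4", "C5", "C6")]
                    if resname in _PURINES
                    else [("N1", "C2", "N3", "C4", "C5", "C6")])
            cls = "nucleic"
        else:
            continue
        for ring_names in defs:
            if all(n in names for n in ring_names):
                cen = np.mean([names[n].position for n in ring_names], axis=0)
                rings.append((cls, cen, key))
    for x in range(len(rings)):
        for y in range(x + 1, len(rings)):
            ca, cen_a, key_a = rings[x]
            cb, cen_b, key_b = rings[y]
            if key_a == key_b:
                continue
            if scope == "inter" and {ca, cb} != {"protein", "nucleic"}:
                continue
            if float(np.linalg.norm(cen_a - cen_b)) <= 5.0:
                counts["aromatic"] += 1
    return counts


# --- metric formulas --------------------------------------------------------

def formula_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / math.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def formula_spearman(x, y):
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), float)
        i = 0
        sv = np.asarray(v, float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    return formula_pearson(ranks(x), ranks(y))


def formula_kendall_tau_b(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v):
    from collections import Counter

    return sum(c * (c - 1) / 2 for c in Counter(np.asarray(v).tolist()).values())


def formula_rmse(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(math.sqrt(np.mean((x - y) ** 2)))


def formula_auc(labels, scores):
    """Probability a positive outscores a negative (ties count half)."""
    pos = [s for lab, s in zip(labels, scores) if lab]
    neg = [s for lab, s in zip(labels, scores) if not lab]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def formula_confusion(tp, fp, tn, fn):
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn) if tp + fp + tn + fn else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return {"sen": sen, "spe": spe, "pre": pre, "acc": acc, "f1": f1,
            "mcc": mcc}
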