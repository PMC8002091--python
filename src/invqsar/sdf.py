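"""SDF (MDL molfile V2000) reading and writing.

Reading suppresses explicit hydrogens and applies the data-curation rules:
records with at most three carbon atoms, charged atoms, isotopes, unknown
elements, aromatic/query bonds, or valences inconsistent with the element
table are skipped with a reason, never aborting the batch.  Writing emits
V2000 records; hydrogens stay implicit via each atom's hydro-degree.
"""

from __future__ import annotations

import csv as _csv
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit import RDLogger

from .chemgraph import ChemGraph, ChemGraphError, DEFAULT_TABLE, Dataset, ElementTable

RDLogger.DisableLog("rdApp.*")

_BOND_TYPES = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


def _mol_to_graph(
    mol, table: ElementTable, curate: bool = True
) -> Tuple[Optional[ChemGraph], Optional[str], str]:
    """Returns (graph, skip_reason, title)."""
    title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    keep: List[int] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if atom.GetFormalCharge() != 0:
            return None, f"charged element {sym}{atom.GetFormalCharge():+d}", title
        if atom.GetIsotope() != 0:
            return None, "isotope label", title
        if sym == "H":
            continue
        if sym not in table:
            return None, f"element {sym} outside the element table", title
        keep.append(atom.GetIdx())
    idx = {a: i for i, a in enumerate(keep)}
    alpha = [mol.GetAtomWithIdx(a).GetSymbol() for a in keep]
    if curate and alpha.count("C") <= 3:
        return None, "at most three carbon atoms", title
    edges, beta = [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if u not in idx or v not in idx:
            continue  # bond to a suppressed hydrogen
        order = bond.GetBondTypeAsDouble()
        if order not in (1.0, 2.0, 3.0):
            return None, f"unsupported bond order {order}", title
        edges.append((idx[u], idx[v]))
        beta.append(int(order))
    try:
        G = ChemGraph(len(keep), edges, alpha, beta, table)
    except ChemGraphError as exc:
        return None, f"invalid chemical graph: {exc}", title
    return G, None, title


def read_sdf(
    path, table: ElementTable = DEFAULT_TABLE, curate: bool = True
) -> Tuple[List[ChemGraph], List[str], List[str]]:
    """Parse an SDF file into chemical graphs.

    Returns (graphs, titles, skip_log); the skip log has one entry per
    rejected record.  With ``curate`` the data-set rules (>3 carbon atoms)
    apply; disable it when reading back inferred structures.
    """
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    graphs: List[ChemGraph] = []
    titles: List[str] = []
    skip_log: List[str] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            skip_log.append(f"record {i}: malformed molfile")
            continue
        G, reason, title = _mol_to_graph(mol, table, curate)
        if G is None:
            skip_log.append(f"record {i} ({title or 'untitled'}): {reason}")
            continue
        graphs.append(G)
        titles.append(title or f"record-{i}")
    return graphs, titles, skip_log


def write_sdf(graphs: Sequence[ChemGraph], path, titles: Optional[Sequence[str]] = None):
    """Write graphs as V2000 SDF records with implicit hydrogens."""
    with open(path, "w") as fh:
        for i, G in enumerate(graphs):
            mol = Chem.RWMol()
            for v in range(G.n):
                atom = Chem.Atom(G.alpha[v])
                atom.SetNumExplicitHs(G.hydro_degree(v))
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
            for (u, v) in G.edges:
                mol.AddBond(u, v, _BOND_TYPES[float(G.beta[(u, v)])])
            m = mol.GetMol()
            m.SetProp("_Name", titles[i] if titles else f"mol-{i}")
            Chem.FastFindRings(m)
            fh.write(Chem.MolToMolBlock(m, kekulize=False))
            fh.write("$$$$\n")


def read_values(path) -> Tuple[Dict[str, float], List[float]]:
    """Property CSV: columns (name,value) or (index,value) or bare values."""
    by_name: Dict[str, float] = {}
    ordered: List[float] = []
    with open(path) as fh:
        reader = _csv.reader(fh)
        rows = [r for r in reader if r]
    start = 0
    header = [c.strip().lower() for c in rows[0]]
    has_name = len(rows[0]) >= 2 and header[0] in ("name", "id", "cid")
    try:
        float(rows[0][-1])
    except ValueError:
        start = 1  # header row
    for row in rows[start:]:
        val = float(row[-1])
        ordered.append(val)
        if len(row) >= 2:
            by_name[row[0].strip()] = val
    return by_name, ordered


def load_dataset(
    sdf_path,
    csv_path,
    property_name: str = "property",
    table: ElementTable = DEFAULT_TABLE,
) -> Dataset:
    """Pair an SDF structure file with a property CSV.

    Values are matched by record title when the CSV has a name column,
    otherwise by record order (over all records, including skipped ones
    when the counts line up, else over kept records).
    """
    graphs, titles, skip_log = read_sdf(sdf_path, table)
    by_name, ordered = read_values(csv_path)
    values: List[float] = []
    kept: List[ChemGraph] = []
    if by_name and all(t in by_name for t in titles):
        for g, t in zip(graphs, titles):
            kept.append(g)
            values.append(by_name[t])
    else:
        if len(ordered) < len(graphs):
            raise ChemGraphError(
                f"{len(ordered)} values for {len(graphs)} kept structures"
            )
        kept = graphs
        values = ordered[: len(graphs)]
    return Dataset(kept, values, property_name, skip_log)
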