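"""Reading and writing macromolecular coordinate files.

Parsing (PDB fixed-column and mmCIF) is delegated to gemmi; the result is
converted into the package's own hierarchy (:class:`~strandslip.model.StructureModel`).
Policy applied on read:

* hydrogens are dropped (crystal structures at ~2 Å rarely model them);
* alternate locations are resolved to a single conformer — highest occupancy
  wins, ties broken by alphabetical altloc id;
* waters and non-polypeptide heteroatoms are kept in the model but flagged,
  and excluded from protein selections by default;
* missing (disordered) residues are simply absent from their chain.

Output is PDB fixed-column only; a read→write→read round trip reproduces
coordinates to 3 decimals and B-factors to 2 decimals (the format's precision).
"""

from __future__ import annotations

import os

import gemmi

from .model import (
    AtomRecord,
    Chain,
    Domain,
    DomainDefinition,
    Residue,
    StructureError,
    StructureModel,
    THREE_TO_ONE,
)

__all__ = ["read_structure", "write_structure", "extract_domain"]


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, then lowest altloc."""
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
            order.append(a.name)
        elif (a.occupancy, _altloc_rank(a.alt_loc)) > (
            prev.occupancy,
            _altloc_rank(prev.alt_loc),
        ):
            by_name[a.name] = a
    for a in by_name.values():
        a.alt_loc = ""
    return [by_name[n] for n in order]


def _altloc_rank(alt_loc: str) -> float:
    # Higher is better; 'A' must beat 'B' at equal occupancy.
    return -ord(alt_loc) if alt_loc else 0.0


def _validate_pdb_lines(path: str) -> None:
    """Reject malformed fixed-column ATOM/HETATM records (gemmi is lenient)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureError(f"{path}:{lineno}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise StructureError(
                    f"{path}:{lineno}: unparseable coordinate line"
                ) from None


def read_structure(path: str | os.PathLike, format_hint: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Coordinate file. The format is taken from ``format_hint``
        (``"pdb"`` or ``"mmcif"``) or, if omitted, from the file contents.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = gemmi.CoorFormat.Unknown
    if format_hint is not None:
        fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}.get(
            format_hint.lower(), gemmi.CoorFormat.Unknown
        )
    is_mmcif = format_hint == "mmcif" or (
        format_hint is None and path.lower().endswith((".cif", ".mmcif"))
    )
    if not is_mmcif:
        _validate_pdb_lines(path)
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        # gemmi error messages carry the offending line/context
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or sum(ch.count_atom_sites() for ch in st[0]) == 0:
        raise StructureError(f"{path}: no atoms in model")

    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    model = StructureModel(id=st.name or os.path.basename(path), chains=[], source_format=source_format)
    gmodel = st[0]  # first model only; NMR ensembles out of scope
    for gchain in gmodel:
        chain = Chain(id=gchain.name)
        seen: set[tuple[int, str]] = set()
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            key = (gres.seqid.num, icode)
            if key in seen:
                raise StructureError(
                    f"{path}: duplicate residue {gchain.name}/{gres.name}{gres.seqid.num}{icode}"
                )
            seen.add(key)
            is_polymer = gres.name in THREE_TO_ONE or (
                gres.het_flag != "H" and not gres.is_water()
            )
            res = Residue(
                chain_id=gchain.name,
                seq_number=gres.seqid.num,
                insertion_code=icode,
                res_name=gres.name,
                is_hetero=not is_polymer and not gres.is_water(),
            )
            raw: list[AtomRecord] = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                raw.append(
                    AtomRecord(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name.upper(),
                        alt_loc=ga.altloc if ga.altloc != "\x00" else "",
                        coords=[ga.pos.x, ga.pos.y, ga.pos.z],
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        b_factor=ga.b_iso,
                    )
                )
            res.atoms = _resolve_altlocs(raw)
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if not model.chains:
        raise StructureError(f"{path}: empty model")
    return model


def extract_domain(model: StructureModel, domain_def: DomainDefinition) -> Domain:
    """Select the residues of ``model`` falling in the domain's ranges.

    Order is preserved; residues missing from the chain (disordered spans)
    are tolerated. Waters and heteroatoms are never part of a domain.
    """
    chain = model.chain(domain_def.chain_id)
    picked = [
        r
        for r in chain.residues
        if not (r.is_water or r.is_hetero) and domain_def.contains(r.seq_number)
    ]
    if not picked:
        raise StructureError(
            f"domain {domain_def.label}: no residues selected on chain {domain_def.chain_id}"
        )
    return Domain(label=domain_def.label, residues=picked)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise StructureError(f"atom name {name!r} longer than 4 characters")
    # Standard PDB alignment: 1-char elements start in column 14
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(model: StructureModel, path: str | os.PathLike) -> None:
    """Write the model as fixed-column PDB (ATOM/HETATM/TER/END)."""
    lines: list[str] = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            record = "HETATM" if (res.is_water or res.is_hetero) else "ATOM  "
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.alt_loc or ' '}{res.res_name:>3s} {chain.id[:1]}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        last = chain.residues[-1]
        lines.append(
            f"TER   {serial:5d}      {last.res_name:>3s} {chain.id[:1]}"
            f"{last.seq_number:4d}{last.insertion_code or ' ':1s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
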