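"""SBML Level 3 Version 1 export of pathway candidates (via libsbml).

One species per metabolite touched by an active reaction (pool members are
flagged boundaryCondition=true, i.e. clamped), one reaction element per
active directed reaction with its full stoichiometry. Identifiers that are
not valid SBML SIds are escaped with a reversible ``_xHH_`` hex mapping.
"""

from __future__ import annotations

import logging
import re

import libsbml

from .milp import PathwaySolution
from .network import MetabolicNetwork

__all__ = ["export_sbml", "sanitize_id", "unsanitize_id", "read_sbml_stoichiometries"]

log = logging.getLogger(__name__)

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def sanitize_id(raw: str) -> str:
    """Map an arbitrary identifier to a valid SBML SId, reversibly.

    Invalid characters become ``_xHH_`` (hex code); a leading digit gets a
    ``_`` prefix encoded the same way. ``unsanitize_id`` inverts the
    mapping. Underscores followed by ``x`` are escaped too so the mapping
    stays injective.
    """
    if _SID_OK.match(raw) and "_x" not in raw:
        return raw
    # escape every char that is not a plain letter/digit (underscores too,
    # so decoding "_xHH_" runs is unambiguous); a leading digit is escaped
    # as well, which leaves the result starting with "_"
    out = []
    for k, ch in enumerate(raw):
        if re.match(r"[A-Za-z0-9]", ch) and not (k == 0 and ch.isdigit()):
            out.append(ch)
        else:
            out.append(f"_x{ord(ch):02x}_")
    s = "".join(out)
    log.info("sanitized SBML id %r -> %r", raw, s)
    return s


def unsanitize_id(sid: str) -> str:
    return re.sub(r"_x([0-9a-f]{2})_", lambda m: chr(int(m.group(1), 16)), sid)


def export_sbml(candidate: PathwaySolution, network: MetabolicNetwork) -> str:
    """Serialize a candidate as an SBML L3V1 document string."""
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("pathway_candidate")

    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    pool = network.categories.pool
    species = sorted(
        {
            m
            for rid in candidate.active_reactions
            for m, _ in network.reaction(rid).coeffs
        }
    )
    for m in species:
        sp = model.createSpecies()
        sp.setId(sanitize_id(m))
        sp.setName(m)
        sp.setCompartment("c")
        sp.setBoundaryCondition(m in pool)
        sp.setHasOnlySubstanceUnits(True)
        sp.setConstant(False)
        sp.setInitialAmount(0.0)

    for rid in sorted(candidate.active_reactions):
        r = network.reaction(rid)
        rx = model.createReaction()
        rx.setId(sanitize_id(rid))
        rx.setName(r.source_id)
        rx.setReversible(False)
        rx.setFast(False)
        for m, c in sorted(r.coeffs):
            ref = rx.createReactant() if c < 0 else rx.createProduct()
            ref.setSpecies(sanitize_id(m))
            ref.setStoichiometry(abs(c))
            ref.setConstant(True)
    return libsbml.writeSBMLToString(doc)


def read_sbml_stoichiometries(text: str) -> dict[str, dict[str, float]]:
    """Parse an SBML string back into reaction -> {metabolite: signed coeff}.

    Identifiers are un-escaped, so a round trip through
    :func:`export_sbml` reproduces the original directed reactions.
    """
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(doc.getErrorLog().toString())
    model = doc.getModel()
    out: dict[str, dict[str, float]] = {}
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        coeffs: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            coeffs[unsanitize_id(ref.getSpecies())] = -ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            coeffs[unsanitize_id(ref.getSpecies())] = ref.getStoichiometry()
        out[unsanitize_id(rx.getId())] = coeffs
    return out
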