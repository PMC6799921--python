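"""Term registry for the OBI_IEE application profile.

The profile grafts terms from fifteen external OBO-style ontologies onto
the Ontology for Biomedical Investigations and adds project-specific
("NEW") classes, arranged as six directed root trees: *assay*, *device*,
*cell*, *anatomical entity*, *organism* and *transformed data set*.  The
registry enumerates only the classes that are individually named in the
profile's published description; the full per-source class counts live in
a declared import manifest, so declared counts are always >= enumerated
counts.

External accessions are indicative: standard CURIEs are used where the
term is unambiguous (e.g. ``CL:0000601`` outer hair cell,
``NCBITaxon:10141`` Cavia porcellus); the remainder carry stable
project-assigned placeholder accessions, since the profile description
names the classes but not their accessions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from .errors import TermNotFoundError, UnknownSourceError

EXTERNAL_SOURCES = (
    "CHEBI", "CL", "CNO", "EDAM", "FMA", "GO", "MP", "NCBITaxon",
    "NCIT", "OBA", "OPB", "PATO", "SBO", "SIO", "UBERON",
)
SOURCES = EXTERNAL_SOURCES + ("OBI", "NEW")

#: declared number of imported classes per external source, plus NEW
DEFAULT_MANIFEST_COUNTS = {
    "CHEBI": 8, "CL": 5, "CNO": 2, "EDAM": 2, "FMA": 12, "GO": 6,
    "MP": 5, "NCBITaxon": 2, "NCIT": 2, "OBA": 7, "OPB": 1, "PATO": 28,
    "SBO": 1, "SIO": 3, "UBERON": 2,
}
DEFAULT_NEW_COUNT = 37

#: IRI base per source, used both for term IRIs and consistency checks
IRI_BASES = {
    "CHEBI": "http://purl.obolibrary.org/obo/CHEBI_",
    "CL": "http://purl.obolibrary.org/obo/CL_",
    "CNO": "https://bioportal.bioontology.org/ontologies/CNO#CNO_",
    "EDAM": "http://edamontology.org/",
    "FMA": "http://purl.obolibrary.org/obo/FMA_",
    "GO": "http://purl.obolibrary.org/obo/GO_",
    "MP": "http://purl.obolibrary.org/obo/MP_",
    "NCBITaxon": "http://purl.obolibrary.org/obo/NCBITaxon_",
    "NCIT": "http://purl.obolibrary.org/obo/NCIT_",
    "OBA": "http://purl.obolibrary.org/obo/OBA_",
    "OPB": "https://bioportal.bioontology.org/ontologies/OPB#OPB_",
    "PATO": "http://purl.obolibrary.org/obo/PATO_",
    "SBO": "http://purl.obolibrary.org/obo/SBO_",
    "SIO": "http://semanticscience.org/resource/SIO_",
    "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
    "OBI": "http://purl.obolibrary.org/obo/",
    "NEW": "https://w3id.org/obi-iee/OBI_IEE_",
}

ROOT_LABELS = (
    "assay", "device", "cell", "anatomical entity", "organism",
    "transformed data set",
)


@dataclass(frozen=True)
class Term:
    """One ontology class with its provenance."""

    id: str
    label: str
    source: str
    parents: frozenset[str] = frozenset()
    definition: str = ""
    iri: str = ""

    def __post_init__(self):
        if not self.label:
            raise ValueError("term label must be nonempty")
        if self.source not in SOURCES:
            raise UnknownSourceError(f"unknown source: {self.source!r}")


@dataclass(frozen=True)
class ImportManifest:
    """Declared per-source import counts plus the declared NEW count.

    Totals are always recomputed from the counts, never stored.
    """

    counts: dict = field(default_factory=dict)
    new_count: int = 0

    def __post_init__(self):
        for src, n in self.counts.items():
            if src not in EXTERNAL_SOURCES:
                raise UnknownSourceError(f"unknown external source: {src!r}")
            if n < 0:
                raise ValueError("declared count must be nonnegative")

    def declared(self, source: str) -> int:
        if source == "NEW":
            return self.new_count
        if source not in EXTERNAL_SOURCES:
            raise UnknownSourceError(f"unknown source: {source!r}")
        return self.counts.get(source, 0)


@dataclass
class TermRegistry:
    """Map of term id -> Term, the six arm-root ids, and the manifest."""

    terms: dict[str, Term]
    roots: tuple[str, ...]
    manifest: ImportManifest

    def __post_init__(self):
        if len(self.roots) != 6:
            raise ValueError("registry must have exactly six arm roots")
        self._check_graph()

    # -- graph sanity ---------------------------------------------------
    def _check_graph(self):
        roots = set(self.roots)
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise TermNotFoundError(f"parent {p!r} of {t.id!r} unknown")
            if t.id not in roots and not t.parents:
                raise ValueError(f"non-root term {t.id!r} has no parents")
        # acyclicity + root reachability by memoised ancestor walk
        state: dict[str, int] = {}

        def reaches_root(tid, stack):
            if tid in roots:
                return True
            if tid in stack:
                raise ValueError(f"cycle through term {tid!r}")
            got = state.get(tid)
            if got is not None:
                return got
            stack = stack | {tid}
            ok = any(reaches_root(p, stack) for p in self.terms[tid].parents)
            state[tid] = ok
            return ok

        for tid in self.terms:
            if not reaches_root(tid, frozenset()):
                raise ValueError(f"term {tid!r} unreachable from any arm root")

    def term(self, tid: str) -> Term:
        try:
            return self.terms[tid]
        except KeyError:
            raise TermNotFoundError(tid) from None

    def by_label(self, label: str) -> Term:
        for t in self.terms.values():
            if t.label == label:
                return t
        raise TermNotFoundError(label)

    def children(self, tid: str) -> list[Term]:
        kids = [t for t in self.terms.values() if tid in t.parents]
        return sorted(kids, key=lambda t: (t.label.lower(), t.id))


# ---------------------------------------------------------------------------
# built-in profile
# ---------------------------------------------------------------------------

# (label, source, accession-or-None, (parent labels...), definition)
# NEW terms get ids assigned in case-insensitive label-sorted order.
_BUILTIN: list[tuple] = [
    # arm roots
    ("assay", "OBI", "OBI:0000070", (),
     "A planned process that produces information about a material entity."),
    ("device", "OBI", "OBI:0000968", (),
     "A processed material designed to perform a function."),
    ("cell", "CL", "CL:0000000", (),
     "A membrane-bounded biological unit; the material entity interrogated."),
    ("anatomical entity", "UBERON", "UBERON:0001062", (),
     "A biological entity that is part of an organism's structural plan."),
    ("organism", "OBI", "OBI:0100026", (),
     "A material entity that is an individual living system."),
    ("transformed data set", "NEW", None, (),
     "A data set produced upon the use of one or more data transformation "
     "processes applied to measurement data."),

    # -- cell arm -----------------------------------------------------------
    ("outer hair cell", "CL", "CL:0000601", ("cell",),
     "The electromotile sensory hair cell of the organ of Corti whose "
     "lateral membrane carries voltage-dependent charge movement."),
    ("morphology", "PATO", "PATO:0000051", ("outer hair cell",),
     "A quality of a material entity pertaining to its form."),
    ("size", "PATO", "PATO:0000117", ("morphology",),
     "A morphological quality pertaining to physical magnitude."),
    ("cell diameter", "OBA", "OBA:0000055", ("size",),
     "The diameter of the interrogated cell, measured from an image."),
    ("cochlear outer hair cell length", "OBA", "OBA:0000444", ("size",),
     "The apex-to-base length of the outer hair cell."),
    ("cochlear outer hair cell lateral wall length", "NEW", None, ("size",),
     "The length of the outer hair cell lateral wall; sibling of cochlear "
     "outer hair cell length."),
    ("cell surface area", "OBA", "OBA:0000056", ("size",),
     "The membrane surface area of the cell, predicted from length and "
     "diameter measurements."),
    ("measurement datum", "OBI", "IAO:0000109",
     ("morphology", "whole-cell patch-clamp voltage clamp assay"),
     "A data item that is the output of a measurement process."),
    ("predicted data item", "OBI", "OBI:0302867",
     ("morphology", "whole-cell patch-clamp voltage clamp assay"),
     "A data item produced by a prediction from a model rather than by "
     "direct measurement."),

    # -- anatomical arm -----------------------------------------------------
    ("subdivision of bony labyrinth", "FMA", "FMA:0060202",
     ("anatomical entity",),
     "An anatomical subdivision of the bony labyrinth of the inner ear."),
    ("subdivision of cochlea", "FMA", "FMA:0060203",
     ("subdivision of bony labyrinth",),
     "An anatomical subdivision of the cochlea."),
    ("cochlea", "UBERON", "UBERON:0001844", ("subdivision of cochlea",),
     "The spiral auditory organ of the inner ear; recorded as left or "
     "right."),
    ("cochlear turn", "NEW", None, ("subdivision of cochlea",),
     "The turn of the cochlear spiral from which the cell originated."),
    ("position", "PATO", "PATO:0000140", ("anatomical entity",),
     "A spatial quality describing placement along an axis."),
    ("apical", "NEW", None, ("position",),
     "Positional origin toward the low-frequency apex of the cochlea."),
    ("basal", "NEW", None, ("position",),
     "Positional origin toward the high-frequency base of the cochlea."),

    # -- organism arm -------------------------------------------------------
    ("Cavia porcellus", "NCBITaxon", "NCBITaxon:10141", ("organism",),
     "The domestic guinea pig."),
    ("sex", "PATO", "PATO:0000047", ("organism",),
     "The biological sex of the animal."),
    ("age", "PATO", "PATO:0000011", ("organism",),
     "The age of the animal at the time of the experiment."),
    ("weight", "PATO", "PATO:0000128", ("organism",),
     "The body weight of the animal."),
    ("phenotype", "MP", "MP:0000001", ("organism",),
     "The observable phenotype of the animal (e.g. pigmented, albino)."),

    # -- assay arm ----------------------------------------------------------
    ("whole-cell patch-clamp voltage clamp assay", "OBI", "OBI:0002177",
     ("assay",),
     "A planned process in which an isolated cell is whole-cell "
     "voltage-clamped and its electrical properties recorded."),
    ("protocol", "OBI", "OBI:0000272",
     ("whole-cell patch-clamp voltage clamp assay",),
     "A plan specification of the stimulus and acquisition sequence."),
    ("electrical admittance dual-sine stimulus", "NEW", None, ("protocol",),
     "Protocol measuring complex electrical admittance under a two-sine "
     "stimulus superposed on a stepped DC command potential."),
    ("membrane current I as a function of membrane potential V", "NEW", None,
     ("protocol",),
     "Protocol measuring membrane current in response to a DC voltage-step "
     "function (I vs V plot)."),
    ("intracellular electrophysiology stimulus", "NEW", None,
     ("electrical admittance dual-sine stimulus",
      "membrane current I as a function of membrane potential V"),
     "The stimulus delivered to the cell: sine frequencies and amplitudes, "
     "DC command potentials and their hold time."),
    ("frequency", "PATO", "PATO:0000044",
     ("intracellular electrophysiology stimulus",),
     "The frequency of a stimulus sine wave."),
    ("amplitude", "PATO", "PATO:0001546",
     ("intracellular electrophysiology stimulus",),
     "The amplitude of a stimulus sine wave."),
    ("time", "PATO", "PATO:0000165",
     ("intracellular electrophysiology stimulus",),
     "The duration for which each command potential is held."),
    ("membrane potential", "OPB", "OPB:00506",
     ("intracellular electrophysiology stimulus",),
     "The electrical potential difference across the cell membrane."),
    ("electrical admittance", "NEW", None, ("measurement datum",),
     "The complex ratio of membrane current to command voltage, measured "
     "at both stimulus frequencies."),
    ("real component of electrical admittance", "NEW", None,
     ("electrical admittance",),
     "The real (conductive) part of the complex electrical admittance."),
    ("imaginary component of electrical admittance", "NEW", None,
     ("electrical admittance",),
     "The imaginary (susceptive) part of the complex electrical "
     "admittance."),
    ("charge flow rate", "SBO", "SBO:0000064", ("measurement datum",),
     "The membrane current measured during the voltage-step protocol."),
    ("membrane capacitance", "CNO", "CNO:0000101", ("predicted data item",),
     "The capacitance of the cell membrane, calculated from the admittance "
     "at each command potential and at both frequencies."),
    ("membrane resistance", "CNO", "CNO:0000102", ("predicted data item",),
     "The resistance of the cell membrane, calculated from the admittance."),
    ("series resistance", "NEW", None, ("predicted data item",),
     "The access resistance of the patch pipette path, calculated from the "
     "admittance."),
    ("study design control variable", "NEW", None,
     ("whole-cell patch-clamp voltage clamp assay",),
     "An experimental variable held under control and reported with the "
     "assay."),
    ("temperature", "PATO", "PATO:0000146",
     ("study design control variable",),
     "The bath temperature during the recording."),
    ("pipette pressure", "NEW", None, ("study design control variable",),
     "The pressure applied to the patch pipette."),
    ("extracellular solution", "NEW", None,
     ("whole-cell patch-clamp voltage clamp assay",),
     "The chemical solution bathing the cell."),
    ("solution in the patch pipette", "NEW", None,
     ("whole-cell patch-clamp voltage clamp assay",),
     "The chemical solution filling the patch pipette."),
    ("concentration", "EDAM", "EDAM:data_2140",
     ("extracellular solution", "solution in the patch pipette"),
     "The molarity of a chemical component of a solution."),
    ("acidity", "PATO", "PATO:0001428",
     ("extracellular solution", "solution in the patch pipette"),
     "The pH of a solution."),
    ("osmolality", "PATO", "PATO:0002027",
     ("extracellular solution", "solution in the patch pipette"),
     "The osmolality of a solution."),
    # solution components (CHEBI)
    ("sodium chloride", "CHEBI", "CHEBI:26710", ("concentration",),
     "NaCl, a principal extracellular electrolyte."),
    ("potassium chloride", "CHEBI", "CHEBI:32588", ("concentration",),
     "KCl, a principal intracellular electrolyte."),
    ("calcium dichloride", "CHEBI", "CHEBI:3312", ("concentration",),
     "CaCl2, divalent-cation source in the bath."),
    ("magnesium dichloride", "CHEBI", "CHEBI:6636", ("concentration",),
     "MgCl2, divalent-cation source."),
    ("HEPES", "CHEBI", "CHEBI:42334", ("concentration",),
     "Zwitterionic pH buffer."),
    ("EGTA", "CHEBI", "CHEBI:30740", ("concentration",),
     "Calcium chelator used in the pipette solution."),
    ("D-glucose", "CHEBI", "CHEBI:17634", ("concentration",),
     "Metabolic substrate added to the bath."),
    ("caesium chloride", "CHEBI", "CHEBI:63039", ("concentration",),
     "CsCl, potassium-channel blocker used in the pipette solution."),

    # -- device arm ---------------------------------------------------------
    ("pipette pressure clamp", "NEW", None, ("device",),
     "The device clamping the pressure applied to the patch pipette."),
    ("patch pipette", "NEW", None, ("device",),
     "The glass pipette forming the gigaohm seal with the cell."),
    ("analog camera", "NEW", None, ("device",),
     "The camera used to image the cell for morphological measurements."),
    ("image", "EDAM", "EDAM:data_2968", ("analog camera",),
     "The image from which cell morphology was measured."),

    # -- transformed data set arm --------------------------------------------
    ("linear data set", "NEW", None, ("transformed data set",),
     "The voltage-independent quantities derived from the dual-sine "
     "protocol."),
    ("non-linear data set", "NEW", None, ("transformed data set",),
     "The voltage-dependent quantities derived from the dual-sine "
     "protocol."),
    ("2-state Boltzmann fit data set", "NEW", None, ("transformed data set",),
     "Parameters predicted by fitting the capacitance or displacement "
     "charge versus membrane potential to the 2-state Boltzmann function."),
    ("IV data set", "NEW", None, ("transformed data set",),
     "The quantities derived from the voltage-step (I vs V) protocol."),
    ("linear membrane capacitance", "NEW", None, ("linear data set",),
     "The voltage-independent component of the membrane capacitance."),
    ("voltage drop across the membrane", "NEW", None, ("linear data set",),
     "The membrane potential after correcting the command potential for "
     "the series-resistance voltage divider."),
    ("non-linear membrane capacitance", "NEW", None, ("non-linear data set",),
     "The voltage-dependent (bell-shaped) component of the membrane "
     "capacitance, including its peak value."),
    ("displacement charge", "NEW", None, ("non-linear data set",),
     "The voltage-dependent charge moved across the membrane, including "
     "its maximum."),
    ("potential of maximum sensitivity", "NEW", None,
     ("2-state Boltzmann fit data set", "non-linear data set"),
     "The membrane potential at which the non-linear capacitance peaks "
     "(V_0.5, V_peak or V_pk)."),
    ("sensitivity of a process to voltage", "NEW", None,
     ("2-state Boltzmann fit data set", "non-linear data set"),
     "The voltage sensitivity (alpha) of the 2-state Boltzmann relation."),
]


def _iri_for(source: str, accession: str) -> str:
    base = IRI_BASES[source]
    local = accession.split(":", 1)[1]
    if source == "EDAM":
        return base + local
    if source == "OBI":
        return "http://purl.obolibrary.org/obo/" + accession.replace(":", "_")
    return base + local


def build_default_registry() -> TermRegistry:
    """Build the registry of profile-named classes plus the Table-style
    declared import manifest."""
    new_labels = sorted(
        (lbl for lbl, src, *_ in _BUILTIN if src == "NEW"),
        key=str.lower,
    )
    new_ids = {lbl: f"OBI_IEE:{i + 1:04d}" for i, lbl in enumerate(new_labels)}

    label_to_id = {}
    for label, source, acc, _parents, _defn in _BUILTIN:
        label_to_id[label] = new_ids[label] if source == "NEW" else acc

    terms = {}
    for label, source, acc, parents, defn in _BUILTIN:
        tid = label_to_id[label]
        iri = "" if source == "NEW" else _iri_for(source, acc)
        terms[tid] = Term(
            id=tid, label=label, source=source,
            parents=frozenset(label_to_id[p] for p in parents),
            definition=defn, iri=iri,
        )
    roots = tuple(label_to_id[lbl] for lbl in ROOT_LABELS)
    manifest = ImportManifest(
        counts=dict(DEFAULT_MANIFEST_COUNTS), new_count=DEFAULT_NEW_COUNT
    )
    return TermRegistry(terms=terms, roots=roots, manifest=manifest)


def empty_registry() -> TermRegistry:
    """A registry with bare arm roots and a zeroed manifest (testing aid)."""
    reg = build_default_registry()
    terms = {tid: replace(reg.terms[tid], parents=frozenset())
             for tid in reg.roots}
    return TermRegistry(
        terms=terms, roots=reg.roots,
        manifest=ImportManifest(counts={s: 0 for s in EXTERNAL_SOURCES},
                                new_count=0),
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def count_by_source(registry: TermRegistry, source: str,
                    mode: str = "declared") -> int:
    """Count terms from one source, either as declared in the manifest or
    as actually enumerated in the registry."""
    if source not in SOURCES:
        raise UnknownSourceError(f"unknown source: {source!r}")
    if mode == "declared":
        return registry.manifest.declared(source)
    if mode == "enumerated":
        return sum(1 for t in registry.terms.values() if t.source == source)
    raise ValueError(f"unknown mode: {mode!r}")


def manifest_totals(registry: TermRegistry):
    """Return (imported_total, new_total, grand_total, source_count).

    imported_total sums the declared counts of the external sources;
    source_count is how many external sources have a nonzero declaration;
    the grand total is a sum, never a stored number.
    """
    m = registry.manifest
    imported = sum(m.declared(s) for s in EXTERNAL_SOURCES)
    source_count = sum(1 for s in EXTERNAL_SOURCES if m.declared(s) > 0)
    return imported, m.new_count, imported + m.new_count, source_count


def subtree(registry: TermRegistry, root_id: str) -> list[Term]:
    """Deterministic pre-order traversal from ``root_id``; children are
    visited in case-insensitive label order.  Terms with multiple parents
    inside the subtree appear once, at their first pre-order position."""
    root = registry.term(root_id)
    out, seen = [], set()

    def visit(term):
        if term.id in seen:
            return
        seen.add(term.id)
        out.append(term)
        for child in registry.children(term.id):
            visit(child)

    visit(root)
    return out


TABLE_HEADER = "id\tlabel\tsource\tiri\tparents\tdefinition"


def export_term_table(registry: TermRegistry) -> str:
    """Serialize the registry to a TSV table (UTF-8, LF, byte-stable).

    The trailing comment line restates the manifest totals so a reader of
    the bare table can see the declared-versus-enumerated distinction.
    """
    rows = [TABLE_HEADER]
    for tid in sorted(registry.terms):
        t = registry.terms[tid]
        parents = ";".join(sorted(t.parents))
        for fieldval in (t.id, t.label, t.source, t.iri, t.definition):
            if "\t" in fieldval or "\n" in fieldval:
                raise ValueError(f"field not TSV-safe: {fieldval!r}")
        rows.append("\t".join((t.id, t.label, t.source, t.iri, parents,
                               t.definition)))
    imported, new, grand, nsrc = manifest_totals(registry)
    rows.append(f"# Total: imported={imported} new={new} total={grand} "
                f"sources={nsrc}")
    rows.append(f"# Roots: {','.join(registry.roots)}")
    man = registry.manifest
    decl = ";".join(f"{s}={man.declared(s)}" for s in EXTERNAL_SOURCES)
    rows.append(f"# Declared: {decl};NEW={man.new_count}")
    return "\n".join(rows) + "\n"


def parse_term_table(text: str) -> TermRegistry:
    """Inverse of :func:`export_term_table`."""
    roots: tuple[str, ...] = ()
    counts: dict[str, int] = {}
    new_count = 0
    terms = {}
    lines = text.splitlines()
    if not lines or lines[0] != TABLE_HEADER:
        raise ValueError("missing term-table header")
    for line in lines[1:]:
        if not line:
            continue
        if line.startswith("# Roots: "):
            roots = tuple(line[len("# Roots: "):].split(","))
            continue
        if line.startswith("# Declared: "):
            for part in line[len("# Declared: "):].split(";"):
                key, val = part.split("=")
                if key == "NEW":
                    new_count = int(val)
                else:
                    counts[key] = int(val)
            continue
        if line.startswith("#"):
            continue
        tid, label, source, iri, parents, defn = line.split("\t")
        terms[tid] = Term(
            id=tid, label=label, source=source,
            parents=frozenset(p for p in parents.split(";") if p),
            definition=defn, iri=iri,
        )
    return TermRegistry(
        terms=terms, roots=roots,
        manifest=ImportManifest(counts=counts, new_count=new_count),
    )


def export_minimal_owl(registry: TermRegistry) -> str:
    """Serialize the registry as a minimal RDF/XML OWL document.

    Only three axiom shapes are emitted: class declarations, rdfs:subClassOf
    links for the is-a graph, and label/definition annotations.  NEW terms
    are published under the project namespace.
    """
    from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
    from rdflib.namespace import OWL

    g = Graph()
    obo = Namespace("http://purl.obolibrary.org/obo/")
    definition = obo["IAO_0000115"]
    g.bind("owl", OWL)
    g.bind("obo", obo)

    def uri(term: Term) -> URIRef:
        if term.iri:
            return URIRef(term.iri)
        return URIRef(IRI_BASES["NEW"] + term.id.split(":", 1)[1])

    for tid in sorted(registry.terms):
        t = registry.terms[tid]
        u = uri(t)
        g.add((u, RDF.type, OWL.Class))
        g.add((u, RDFS.label, Literal(t.label)))
        if t.definition:
            g.add((u, definition, Literal(t.definition)))
        for p in sorted(t.parents):
            g.add((u, RDFS.subClassOf, uri(registry.terms[p])))
    return g.serialize(format="pretty-xml")
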