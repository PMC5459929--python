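"""Linked-data export of quality records as RDF Turtle.

Each run or experiment record becomes one subject with a type triple, a
``dcterms:identifier`` triple and one numeric triple per metric, so the
statistics can be joined with other life-science linked data through a
triple store.  The vocabulary shipped here is provisional by design: the
predicate names and base URI live in an overridable :class:`RdfMapping`
rather than pretending to be an official ontology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdflib import RDF, Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCTERMS, XSD

from .aggregate import ExperimentQuality
from .qc_metrics import RunQuality

__all__ = ["RdfMapping", "export_rdf", "read_rdf"]

_RUN_FIELDS = (
    "total_reads",
    "total_bases",
    "pct_gc",
    "mean_length",
    "median_length",
    "duplicate_pct",
    "mean_accuracy",
    "median_accuracy",
    "n_content_pct",
)
_EXPERIMENT_FIELDS = ("n_runs",) + _RUN_FIELDS

_INT_FIELDS = {"total_reads", "total_bases", "n_runs"}


@dataclass
class RdfMapping:
    """Base URI, class names and per-field predicate names."""

    base_uri: str = "https://example.org/seqstats/"
    run_class: str = "SequenceRunStatistics"
    experiment_class: str = "SequenceExperimentStatistics"
    predicates: dict = field(default_factory=dict)  # field name -> predicate name

    def predicate(self, name: str) -> str:
        return self.predicates.get(name, name)

    def validate(self, field_names: Sequence[str]) -> None:
        seen: dict[str, str] = {}
        for f in field_names:
            pred = self.predicate(f)
            if pred in seen:
                raise ValueError(
                    f"predicate {pred!r} maps both {seen[pred]!r} and {f!r}"
                )
            seen[pred] = f
        URIRef(self.base_uri)  # syntactic check


def _record_fields(record) -> tuple[str, str, tuple[str, ...]]:
    if isinstance(record, RunQuality):
        return record.run_id, "run", _RUN_FIELDS
    if isinstance(record, ExperimentQuality):
        return record.experiment_id, "experiment", _EXPERIMENT_FIELDS
    raise TypeError(f"cannot export {type(record).__name__}")


def export_rdf(
    records: Sequence[RunQuality | ExperimentQuality],
    out: str | Path,
    mapping: RdfMapping | None = None,
) -> int:
    """Serialize records as Turtle; returns the number of triples written.

    Every record contributes one ``rdf:type`` triple, one
    ``dcterms:identifier`` triple and one triple per set numeric field.
    Records with an unset (None/NaN) required field are skipped with a
    warning rather than emitting partial statistics.
    """
    import warnings

    mapping = mapping or RdfMapping()
    mapping.validate(_EXPERIMENT_FIELDS)
    ns = Namespace(mapping.base_uri)
    g = Graph()
    g.bind("sstat", ns)
    g.bind("dcterms", DCTERMS)

    skipped = 0
    for rec in records:
        rec_id, kind, fnames = _record_fields(rec)
        values = {f: getattr(rec, f) for f in fnames}
        if any(v is None or v != v for v in values.values()):
            skipped += 1
            continue
        subject = URIRef(mapping.base_uri + rec_id)
        cls = mapping.run_class if kind == "run" else mapping.experiment_class
        g.add((subject, RDF.type, ns[cls]))
        g.add((subject, DCTERMS.identifier, Literal(rec_id)))
        for f, v in values.items():
            if f in _INT_FIELDS:
                lit = Literal(int(v), datatype=XSD.integer)
            else:
                lit = Literal(float(v), datatype=XSD.double)
            g.add((subject, ns[mapping.predicate(f)], lit))
    if skipped:
        warnings.warn(f"skipped {skipped} record(s) with unset fields", stacklevel=2)
    g.serialize(destination=str(out), format="turtle")
    return len(g)


def read_rdf(
    path: str | Path, mapping: RdfMapping | None = None
) -> list[RunQuality | ExperimentQuality]:
    """Parse a Turtle file written by :func:`export_rdf` back into records.

    Per-position tables are not part of the RDF representation; runs come
    back with empty tables and an empty length distribution.
    """
    mapping = mapping or RdfMapping()
    ns = Namespace(mapping.base_uri)
    g = Graph()
    g.parse(str(path), format="turtle")

    records = []
    for subject, _, cls in sorted(g.triples((None, RDF.type, None))):
        kind = (
            "run"
            if cls == ns[mapping.run_class]
            else "experiment"
            if cls == ns[mapping.experiment_class]
            else None
        )
        if kind is None:
            continue
        rec_id = str(g.value(subject, DCTERMS.identifier))
        fnames = _RUN_FIELDS if kind == "run" else _EXPERIMENT_FIELDS
        vals = {}
        for f in fnames:
            lit = g.value(subject, ns[mapping.predicate(f)])
            if lit is None:
                raise ValueError(f"{rec_id}: missing predicate {mapping.predicate(f)}")
            vals[f] = int(lit) if f in _INT_FIELDS else float(lit)
        if kind == "run":
            records.append(
                RunQuality(
                    run_id=rec_id,
                    length_distribution={},
                    per_position_quality=[],
                    per_position_n=[],
                    **vals,
                )
            )
        else:
            records.append(ExperimentQuality(experiment_id=rec_id, **vals))
    return records
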