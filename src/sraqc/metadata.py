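"""SRA experiment and BioSample metadata: parsing and joining.

Quality records only become searchable once the submitter-described
categorical metadata (library strategy and source, instrument, organism,
dates) is attached.  Experiments link to organism information through the
ExperimentID <-> BioSampleID relation.  Metadata may come from SRA
EXPERIMENT-set XML and BioSample XML, or from flat TSV files with the same
column names.  Submitter metadata is propagated as-is — it may contain
errors, and correcting it is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
from lxml import etree

__all__ = [
    "ExperimentMetadata",
    "MANUFACTURER_MAP",
    "JoinReport",
    "parse_sra_experiment_xml",
    "parse_biosample_xml",
    "read_metadata_tsv",
    "join_records",
]

#: PLATFORM element name -> instrument manufacturer. Editable: pass your own
#: mapping to parse_sra_experiment_xml for platforms not listed here.
MANUFACTURER_MAP = {
    "ILLUMINA": "Illumina",
    "LS454": "454",
    "PACBIO_SMRT": "PacBio",
    "ION_TORRENT": "IonTorrent",
    "ABI_SOLID": "SOLiD",
    "OXFORD_NANOPORE": "OxfordNanopore",
    "COMPLETE_GENOMICS": "CompleteGenomics",
    "HELICOS": "Helicos",
    "CAPILLARY": "Capillary",
    "BGISEQ": "BGI",
    "DNBSEQ": "BGI",
}

#: column order of the tabular metadata representation
METADATA_COLUMNS = [
    "experiment_id",
    "biosample_id",
    "library_strategy",
    "library_source",
    "instrument_model",
    "manufacturer",
    "taxonomy_id",
    "scientific_name",
    "date",
]


@dataclass
class ExperimentMetadata:
    """Categorical metadata of one experiment, as described by the submitter."""

    experiment_id: str
    biosample_id: str | None = None
    library_strategy: str | None = None
    library_source: str | None = None
    instrument_model: str | None = None
    manufacturer: str | None = None
    taxonomy_id: int | None = None
    scientific_name: str | None = None
    date: str | None = None


@dataclass
class JoinReport:
    """Bookkeeping of a metadata join (nothing is ever dropped silently)."""

    n_quality: int = 0
    n_matched_experiment: int = 0
    n_matched_sample: int = 0
    n_unused_metadata: int = 0
    warnings: list[str] = field(default_factory=list)


def _local(tag) -> str:
    """Tag name with any XML namespace stripped."""
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def _find_local(elem, name: str):
    for node in elem.iter():
        if _local(node.tag) == name:
            return node
    return None


def parse_sra_experiment_xml(
    document: str | bytes,
    manufacturer_map: dict[str, str] | None = None,
) -> list[ExperimentMetadata]:
    """Extract one :class:`ExperimentMetadata` per EXPERIMENT element.

    The manufacturer is derived from the name of the PLATFORM child
    element (e.g. ILLUMINA -> Illumina); unmapped platforms become
    "Unknown".  Missing optional fields stay unset.  Parsing ignores
    namespace prefixes and element order.  EXPERIMENTs without an
    accession are skipped with a warning.
    """
    mmap = manufacturer_map or MANUFACTURER_MAP
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc

    out: list[ExperimentMetadata] = []
    skipped = 0
    for exp in root.iter():
        if _local(exp.tag) != "EXPERIMENT":
            continue
        accession = exp.get("accession")
        if not accession:
            prim = _find_local(exp, "PRIMARY_ID")
            accession = prim.text.strip() if prim is not None and prim.text else None
        if not accession:
            skipped += 1
            continue
        meta = ExperimentMetadata(experiment_id=accession)
        strat = _find_local(exp, "LIBRARY_STRATEGY")
        if strat is not None and strat.text and strat.text.strip():
            meta.library_strategy = strat.text.strip()
        source = _find_local(exp, "LIBRARY_SOURCE")
        if source is not None and source.text and source.text.strip():
            meta.library_source = source.text.strip()
        platform = _find_local(exp, "PLATFORM")
        if platform is not None:
            for child in platform:
                name = _local(child.tag)
                if not name:
                    continue
                meta.manufacturer = mmap.get(name, "Unknown")
                model = _find_local(child, "INSTRUMENT_MODEL")
                if model is not None and model.text:
                    meta.instrument_model = model.text.strip()
                break
        # BioSample link: EXTERNAL_ID with namespace="BioSample", or the
        # SAMPLE_DESCRIPTOR accession as a fallback.
        for node in exp.iter():
            if (
                _local(node.tag) == "EXTERNAL_ID"
                and node.get("namespace") == "BioSample"
                and node.text
            ):
                meta.biosample_id = node.text.strip()
                break
        if meta.biosample_id is None:
            sd = _find_local(exp, "SAMPLE_DESCRIPTOR")
            if sd is not None and sd.get("accession"):
                meta.biosample_id = sd.get("accession")
        for attr in ("published", "date"):
            if exp.get(attr):
                meta.date = exp.get(attr)
                break
        out.append(meta)
    if skipped:
        warnings.warn(f"skipped {skipped} EXPERIMENT(s) without accession", stacklevel=2)
    return out


def parse_biosample_xml(document: str | bytes) -> pd.DataFrame:
    """BioSample accession -> (taxonomy_id, scientific_name) table.

    One row per BioSample; samples without an Organism element keep both
    fields unset.  A repeated accession keeps the last record, with a
    warning.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc

    rows: dict[str, dict] = {}
    dupes = 0
    for sample in root.iter():
        if _local(sample.tag) != "BioSample":
            continue
        accession = sample.get("accession")
        if not accession:
            continue
        tax_id = None
        name = None
        org = _find_local(sample, "Organism")
        if org is not None:
            raw = org.get("taxonomy_id")
            if raw:
                tax_id = int(raw)
            name = org.get("taxonomy_name") or None
            if name is None:
                on = _find_local(org, "OrganismName")
                if on is not None and on.text:
                    name = on.text.strip()
        if accession in rows:
            dupes += 1
        rows[accession] = {
            "biosample_id": accession,
            "taxonomy_id": tax_id,
            "scientific_name": name,
        }
    if dupes:
        warnings.warn(f"{dupes} duplicate BioSample accession(s); last record kept", stacklevel=2)
    return pd.DataFrame(
        list(rows.values()), columns=["biosample_id", "taxonomy_id", "scientific_name"]
    )


def read_metadata_tsv(path: str | Path) -> list[ExperimentMetadata]:
    """Read experiment metadata from a flat TSV with METADATA_COLUMNS names."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "experiment_id" not in df.columns:
        raise ValueError("metadata TSV lacks an experiment_id column")
    valid = {f.name for f in fields(ExperimentMetadata)}
    out = []
    for row in df.to_dict("records"):
        kwargs = {k: v for k, v in row.items() if k in valid and pd.notna(v)}
        if "taxonomy_id" in kwargs:
            kwargs["taxonomy_id"] = int(float(kwargs["taxonomy_id"]))
        out.append(ExperimentMetadata(**kwargs))
    return out


def join_records(
    quality,
    experiments: list[ExperimentMetadata] | None = None,
    samples: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, JoinReport]:
    """Left-join quality records with experiment and sample metadata.

    Quality records (a list of ExperimentQuality or a DataFrame with an
    ``experiment_id`` column) are joined first on experiment_id, then on
    the biosample_id the experiment metadata provides.  Every quality
    record is retained; metadata rows that match nothing are counted in
    the report, never errors.
    """
    report = JoinReport()
    if isinstance(quality, pd.DataFrame):
        qdf = quality.copy()
    else:
        from .serialize import experiments_to_frame

        qdf = experiments_to_frame(quality)
    report.n_quality = len(qdf)

    if experiments:
        mdf = pd.DataFrame(
            [
                {f.name: getattr(m, f.name) for f in fields(ExperimentMetadata)}
                for m in experiments
            ]
        )
        mdf = mdf.drop_duplicates(subset="experiment_id", keep="last")
        joined = qdf.merge(mdf, on="experiment_id", how="left")
        report.n_matched_experiment = int(
            joined["experiment_id"].isin(mdf["experiment_id"]).sum()
        )
        report.n_unused_metadata = int(
            (~mdf["experiment_id"].isin(qdf["experiment_id"])).sum()
        )
    else:
        joined = qdf.copy()
        for col in METADATA_COLUMNS[1:]:
            joined[col] = None

    if samples is not None and not samples.empty and "biosample_id" in joined:
        sdf = samples.drop_duplicates(subset="biosample_id", keep="last")
        sdf = sdf.rename(
            columns={"taxonomy_id": "_tax", "scientific_name": "_sci"}
        )
        joined = joined.merge(sdf, on="biosample_id", how="left")
        for src, dst in (("_tax", "taxonomy_id"), ("_sci", "scientific_name")):
            if src in joined:
                joined[dst] = joined[dst].where(joined[dst].notna(), joined[src])
                joined = joined.drop(columns=src)
        report.n_matched_sample = int(
            joined["biosample_id"].isin(sdf["biosample_id"]).sum()
        )

    if len(joined) != report.n_quality:
        raise AssertionError("join changed the quality row count")
    return joined, report
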