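"""Corpus and label-table I/O.

Three corpus dialects are supported, all plain text: MEDLINE flat files
(``PMID``/``TI``/``AB`` tags, as parsed by Biopython), PubMed XML, and a
simple three-column TSV.  Label tables are TSVs mirroring the published
benchmark files: one row per PMID with the Level-0 curatability call and
the Level 1-3 category names, ``NA`` where a level does not apply.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

from Bio import Medline
from lxml import etree

from .taxonomy import NA, Taxonomy, TaxonomyError

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractRecord",
    "LabelRecord",
    "CorpusError",
    "read_abstracts",
    "write_abstracts",
    "read_label_table",
    "write_label_table",
    "join_corpus",
]

CURATABLE = "curatable"
UNCURATABLE = "uncuratable"
LABEL_HEADER = ["PMID", "LEVEL0", "LEVEL1", "LEVEL2", "LEVEL3"]


class CorpusError(ValueError):
    """Malformed corpus or label file."""


@dataclass(frozen=True)
class AbstractRecord:
    """One citation: PMID, title and (possibly empty) abstract text."""

    pmid: str
    title: str
    abstract: str = ""

    @property
    def text(self) -> str:
        """The classification text: title and abstract concatenated."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class LabelRecord:
    """Expert labels for one PMID across the four levels."""

    pmid: str
    level0: str  # "curatable" | "uncuratable"
    level1: str = NA
    level2: str = NA
    level3: str = NA

    def validate(self, taxonomy: Taxonomy | None = None) -> None:
        if self.level0 not in (CURATABLE, UNCURATABLE):
            raise CorpusError(f"PMID {self.pmid}: bad Level-0 label {self.level0!r}")
        if self.level0 == UNCURATABLE:
            if (self.level1, self.level2, self.level3) != (NA, NA, NA):
                raise CorpusError(
                    f"PMID {self.pmid}: uncuratable rows must have NA at Levels 1-3"
                )
            return
        if taxonomy is not None:
            try:
                taxonomy.validate_path(self.level1, self.level2, self.level3)
            except TaxonomyError as exc:
                raise CorpusError(f"PMID {self.pmid}: {exc}") from exc

    @property
    def path(self) -> tuple[str, str, str]:
        return (self.level1, self.level2, self.level3)


def _check_unique(records: list[AbstractRecord]) -> None:
    seen: dict[str, int] = {}
    dups = []
    for rec in records:
        if rec.pmid in seen:
            dups.append(rec.pmid)
        seen[rec.pmid] = 1
    if dups:
        raise CorpusError(f"duplicate PMIDs: {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# corpus readers / writers

def _read_medline(path) -> list[AbstractRecord]:
    records = []
    with open(path) as fh:
        for i, rec in enumerate(Medline.parse(fh)):
            pmid = rec.get("PMID", "")
            if not pmid:
                raise CorpusError(f"MEDLINE record {i}: missing PMID")
            title = rec.get("TI", "")
            abstract = rec.get("AB", "")
            if not abstract:
                logger.warning("PMID %s has no abstract; keeping title only", pmid)
            records.append(AbstractRecord(pmid, title, abstract))
    return records


def _write_medline(path, records) -> None:
    def wrap(tag: str, text: str) -> str:
        # MEDLINE continuation lines are indented six spaces
        words = text.split()
        if not words:
            return f"{tag:<4}- \n"
        lines, cur = [], f"{tag:<4}- {words[0]}"
        for w in words[1:]:
            if len(cur) + 1 + len(w) > 80:
                lines.append(cur)
                cur = "      " + w
            else:
                cur += " " + w
        lines.append(cur)
        return "\n".join(lines) + "\n"

    with open(path, "w") as fh:
        for rec in records:
            fh.write(wrap("PMID", rec.pmid))
            fh.write(wrap("TI", rec.title))
            if rec.abstract:
                fh.write(wrap("AB", rec.abstract))
            fh.write("\n")


def _read_pubmed_xml(path) -> list[AbstractRecord]:
    tree = etree.parse(str(path))
    records = []
    for i, art in enumerate(tree.iter("PubmedArticle")):
        pmid_el = art.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            raise CorpusError(f"PubmedArticle {i}: missing PMID")
        title = "".join(art.find(".//Article/ArticleTitle").itertext()) if art.find(".//Article/ArticleTitle") is not None else ""
        parts = [
            "".join(el.itertext())
            for el in art.findall(".//Article/Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in parts if p)
        if not abstract:
            logger.warning("PMID %s has no abstract; keeping title only", pmid_el.text)
        records.append(AbstractRecord(pmid_el.text.strip(), title, abstract))
    return records


def _write_pubmed_xml(path, records) -> None:
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract:
            abst = etree.SubElement(article, "Abstract")
            etree.SubElement(abst, "AbstractText").text = rec.abstract
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _read_tsv(path) -> list[AbstractRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"pmid", "title", "abstract"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CorpusError(f"TSV corpus must have columns {sorted(required)}")
        for i, row in enumerate(reader):
            if not row["pmid"]:
                raise CorpusError(f"TSV row {i}: empty pmid")
            if not row["abstract"]:
                logger.warning("PMID %s has no abstract; keeping title only", row["pmid"])
            records.append(AbstractRecord(row["pmid"], row["title"], row["abstract"] or ""))
    return records


def _write_tsv(path, records) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["pmid", "title", "abstract"])
        for rec in records:
            writer.writerow([rec.pmid, rec.title, rec.abstract])


_READERS = {"medline": _read_medline, "pubmed-xml": _read_pubmed_xml, "tsv": _read_tsv}
_WRITERS = {"medline": _write_medline, "pubmed-xml": _write_pubmed_xml, "tsv": _write_tsv}


def read_abstracts(path, format: str = "medline") -> list[AbstractRecord]:
    """Read a corpus file into AbstractRecords.

    Records lacking an abstract are retained with an empty abstract (a
    warning is logged).  Duplicate PMIDs raise :class:`CorpusError`.
    """
    if format not in _READERS:
        raise ValueError(f"unknown corpus format {format!r}; choose from {sorted(_READERS)}")
    records = _READERS[format](path)
    _check_unique(records)
    return records


def write_abstracts(path, records, format: str = "medline") -> None:
    if format not in _WRITERS:
        raise ValueError(f"unknown corpus format {format!r}; choose from {sorted(_WRITERS)}")
    _WRITERS[format](path, list(records))


# ---------------------------------------------------------------------------
# label tables

def read_label_table(path, taxonomy: Taxonomy | None = None) -> list[LabelRecord]:
    """Read a TSV label table; validate paths against ``taxonomy`` if given."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != LABEL_HEADER:
            raise CorpusError(f"label table header must be {LABEL_HEADER}, got {header}")
        for i, row in enumerate(reader):
            if len(row) != 5:
                raise CorpusError(f"label row {i}: expected 5 columns, got {len(row)}")
            rec = LabelRecord(*row)
            rec.validate(taxonomy)
            records.append(rec)
    pmids = [r.pmid for r in records]
    if len(set(pmids)) != len(pmids):
        dups = sorted({p for p in pmids if pmids.count(p) > 1})
        raise CorpusError(f"duplicate PMIDs in label table: {dups}")
    return records


def write_label_table(path, records) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(LABEL_HEADER)
        for rec in records:
            writer.writerow([rec.pmid, rec.level0, rec.level1, rec.level2, rec.level3])


def join_corpus(
    abstracts: list[AbstractRecord], labels: list[LabelRecord]
) -> tuple[list[tuple[AbstractRecord, LabelRecord]], dict]:
    """Inner-join abstracts with labels on PMID.

    Returns the joined pairs (in abstract order) and a report with the
    counts of unmatched PMIDs on both sides.  Zero overlap is an error.
    """
    by_pmid = {lab.pmid: lab for lab in labels}
    joined = [(rec, by_pmid[rec.pmid]) for rec in abstracts if rec.pmid in by_pmid]
    matched = {rec.pmid for rec, _ in joined}
    report = {
        "joined": len(joined),
        "unlabeled_abstracts": len(abstracts) - len(joined),
        "labels_without_abstract": len([l for l in labels if l.pmid not in matched]),
    }
    if abstracts and labels and not joined:
        raise CorpusError("no overlap between abstract PMIDs and label PMIDs")
    if report["unlabeled_abstracts"] or report["labels_without_abstract"]:
        logger.info(
            "join: %(joined)d matched, %(unlabeled_abstracts)d abstracts unlabeled, "
            "%(labels_without_abstract)d labels without abstract", report
        )
    return joined, report
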