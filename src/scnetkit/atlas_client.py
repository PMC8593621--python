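"""REST clients for the Single Cell Expression Atlas (GXA) and the Human
Cell Atlas DCP1 data portal.

Both clients speak through a ``Transport`` -- the live
:class:`HttpTransport` (stdlib urllib, 60 s timeout, 3 retries with
backoff) or a :class:`FixtureTransport` serving recorded payloads -- so
every behavior is reproducible offline.  A :class:`CachingTransport` layer
keyed by URL avoids re-downloading versioned atlas payloads and exposes
hit/miss counters.

GXA endpoints (``%s`` is the accession):

* listing:            ``https://www.ebi.ac.uk/gxa/sc/json/experiments``
* normalized matrix:  ``.../sc/experiment/%s/download/zip?fileType=normalised``
* clusters:           ``.../sc/experiment/%s/download?fileType=cluster``
* experiment design:  ``.../sc/experiment/%s/download?fileType=experiment-design``

HCA DCP1 listing filters to matrix files with the query filter
``{"fileFormat":{"is":["matrix"]}}``; a project with several matrices (one
per tissue/organ) is split into one entry per matrix file.  The DCP2 API
is not implemented and raises on use.
"""

from __future__ import annotations

import io
import json
import tempfile
import time
import urllib.error
import urllib.parse
import urllib.request
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, TransportError, UnknownAccessionError
from .matrix_io import (
    Category,
    CategoryRow,
    ExpressionExperiment,
    attach_category,
    read_category_csv,
    read_mtx_triple,
)

__all__ = [
    "AtlasEntry",
    "HttpTransport",
    "FixtureTransport",
    "CachingTransport",
    "GxaClient",
    "HcaClient",
    "HCA_MATRIX_FILTER",
    "gxa_fixture_payloads",
]

GXA_BASE = "https://www.ebi.ac.uk/gxa/sc"
GXA_EXPERIMENTS_URL = f"{GXA_BASE}/json/experiments"
GXA_MATRIX_URL = f"{GXA_BASE}/experiment/%s/download/zip?fileType=normalised"
GXA_CLUSTERS_URL = f"{GXA_BASE}/experiment/%s/download?fileType=cluster"
GXA_DESIGN_URL = f"{GXA_BASE}/experiment/%s/download?fileType=experiment-design"

HCA_BASE = "https://service.azul.data.humancellatlas.org"
HCA_MATRIX_FILTER = {"fileFormat": {"is": ["matrix"]}}


def hca_projects_url() -> str:
    query = urllib.parse.urlencode(
        {"catalog": "dcp1",
         "filters": json.dumps(HCA_MATRIX_FILTER, separators=(",", ":"))}
    )
    return f"{HCA_BASE}/index/projects?{query}"


@dataclass
class AtlasEntry:
    """One browsable experiment in an atlas listing."""

    accession: str
    description: str
    species: str
    n_cells: int
    source: str  # "GXA" or "HCA"
    download_url: str = ""
    raw: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Transports
# ---------------------------------------------------------------------------


class HttpTransport:
    """Live HTTP GET with timeout and retries (exponential backoff)."""

    def __init__(self, timeout: float = 60.0, retries: int = 3,
                 backoff: float = 1.0):
        self.timeout = timeout
        self.retries = retries
        self.backoff = backoff

    def get(self, url: str) -> bytes:
        last: Exception | None = None
        for attempt in range(self.retries):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read()
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    raise UnknownAccessionError(f"404 for {url}") from exc
                last = exc
            except Exception as exc:  # noqa: BLE001 - retried, then rewrapped
                last = exc
            time.sleep(self.backoff * 2**attempt)
        raise TransportError(f"GET failed after {self.retries} attempts: {url}: {last}")


class FixtureTransport:
    """Serves recorded payloads from a ``{url: bytes}`` mapping."""

    def __init__(self, payloads: dict[str, bytes]):
        self.payloads = dict(payloads)
        self.requests: list[str] = []

    def get(self, url: str) -> bytes:
        self.requests.append(url)
        if url not in self.payloads:
            raise UnknownAccessionError(f"no recorded payload for {url}")
        return self.payloads[url]


class CachingTransport:
    """On-disk cache in front of another transport, keyed by URL."""

    def __init__(self, inner, cache_dir: str | Path):
        self.inner = inner
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.hits = 0
        self.misses = 0

    def _key(self, url: str) -> Path:
        import hashlib

        digest = hashlib.sha256(url.encode()).hexdigest()[:32]
        return self.cache_dir / digest

    def get(self, url: str) -> bytes:
        path = self._key(url)
        if path.exists():
            self.hits += 1
            return path.read_bytes()
        payload = self.inner.get(url)
        self.misses += 1
        path.write_bytes(payload)  # only after a complete download
        return payload


# ---------------------------------------------------------------------------
# GXA
# ---------------------------------------------------------------------------


class GxaClient:
    """Client for the Single Cell Expression Atlas REST interface.

    Pass ``cache_dir`` to cache payloads on disk; atlas payloads are large
    and versioned, so interactive use benefits, while the default stays
    cache-free (no stale state between runs).
    """

    def __init__(self, transport=None, cache_dir: str | Path | None = None):
        transport = transport or HttpTransport()
        if cache_dir is not None and not isinstance(transport, CachingTransport):
            transport = CachingTransport(transport, cache_dir)
        self.transport = transport

    def list_entries(self) -> list[AtlasEntry]:
        """One entry per experiment in the atlas-wide JSON listing."""
        url = GXA_EXPERIMENTS_URL
        payload = self.transport.get(url)
        try:
            doc = json.loads(payload.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise TransportError(f"unparseable JSON from {url}: {exc}") from exc
        experiments = doc.get("experiments", doc) if isinstance(doc, dict) else doc
        if not isinstance(experiments, list):
            raise TransportError(f"unexpected listing shape from {url}")
        entries = []
        for item in experiments:
            accession = item.get("experimentAccession", "")
            if not accession:
                continue
            entries.append(AtlasEntry(
                accession=accession,
                description=item.get("experimentDescription", ""),
                species=item.get("species", ""),
                n_cells=int(item.get("numberOfAssays", 0) or 0),
                source="GXA",
                raw=item,
            ))
        if not entries:
            warnings.warn("GXA listing contained no experiments", stacklevel=2)
        return entries

    def fetch_experiment(self, accession: str) -> ExpressionExperiment:
        """Download matrix + clusters + experiment design for an accession.

        The clusters category reads with ``transpose=False`` (GXA
        orientation) and the experiment design with ``transpose=True``
        (cells in rows); both are attached to the returned experiment.
        """
        matrix_zip = self.transport.get(GXA_MATRIX_URL % accession)
        clusters_raw = self.transport.get(GXA_CLUSTERS_URL % accession)
        design_raw = self.transport.get(GXA_DESIGN_URL % accession)

        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            zip_path = tmpdir / f"{accession}.zip"
            zip_path.write_bytes(matrix_zip)
            species = _species_from_zip(matrix_zip)
            exp = read_mtx_triple(zip_path, species=species,
                                  accession=accession, source="GXA")
            clusters_path = tmpdir / "clusters.tsv"
            clusters_path.write_bytes(clusters_raw)
            clusters = read_category_csv(clusters_path, transpose=False,
                                         name="Cluster")
            design_path = tmpdir / "design.tsv"
            design_path.write_bytes(design_raw)
            design = read_category_csv(design_path, transpose=True,
                                       name="Experiment design")
        attach_category(exp, clusters)
        attach_category(exp, design)
        return exp


def _species_from_zip(payload: bytes) -> str:
    """Best-effort species lookup from an optional metadata member."""
    try:
        with zipfile.ZipFile(io.BytesIO(payload)) as zf:
            for name in zf.namelist():
                if name.endswith("species.txt"):
                    return zf.read(name).decode().strip()
    except zipfile.BadZipFile:
        pass
    return ""


# ---------------------------------------------------------------------------
# HCA (DCP1)
# ---------------------------------------------------------------------------


class HcaClient:
    """Client for the Human Cell Atlas DCP1 data portal (azul index)."""

    def __init__(self, transport=None, cache_dir: str | Path | None = None):
        transport = transport or HttpTransport()
        if cache_dir is not None and not isinstance(transport, CachingTransport):
            transport = CachingTransport(transport, cache_dir)
        self.transport = transport

    def list_entries(self) -> list[AtlasEntry]:
        """One entry per (project x matrix file); projects with several
        matrices -- one per tissue or organ -- are split into independent
        experiments."""
        url = hca_projects_url()
        payload = self.transport.get(url)
        try:
            doc = json.loads(payload.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise TransportError(f"unparseable JSON from {url}: {exc}") from exc
        entries = []
        for hit in doc.get("hits", []):
            projects = hit.get("projects", [])
            title = projects[0].get("projectTitle", "") if projects else ""
            short = projects[0].get("projectShortname", "") if projects else ""
            species = ""
            donors = hit.get("donorOrganisms", [])
            if donors and donors[0].get("genusSpecies"):
                species = donors[0]["genusSpecies"][0]
            cells = 0
            for cs in hit.get("cellSuspensions", []):
                cells += int(cs.get("totalCells", 0) or 0)
            matrices = [f for f in hit.get("fileTypeSummaries", [])
                        if f.get("fileFormat") == "matrix"]
            for i, f in enumerate(matrices):
                suffix = f".{i}" if len(matrices) > 1 else ""
                entries.append(AtlasEntry(
                    accession=(short or title) + suffix,
                    description=title,
                    species=species,
                    n_cells=cells,
                    source="HCA",
                    download_url=f.get("url", ""),
                    raw=hit,
                ))
        if not entries:
            warnings.warn("HCA listing contained no matrix entries", stacklevel=2)
        return entries

    def fetch_experiment(self, entry: AtlasEntry) -> ExpressionExperiment:
        """Download an HCA matrix zip: MatrixMarket files plus a combined
        barcode + categorical-metadata table (one CategoryRow per metadata
        column after the barcode column)."""
        if not entry.download_url:
            raise UnknownAccessionError(
                f"entry {entry.accession!r} carries no matrix download URL"
            )
        payload = self.transport.get(entry.download_url)
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            zip_path = tmpdir / "matrix.zip"
            zip_path.write_bytes(payload)
            exp = read_mtx_triple(zip_path, species=entry.species,
                                  accession=entry.accession, source="HCA")
            category = _hca_barcode_category(zip_path)
        if category is not None:
            attach_category(exp, category)
        return exp

    def fetch_experiment_dcp2(self, *_args, **_kwargs):
        raise NotImplementedError("the HCA DCP2 API is unsupported")


def _hca_barcode_category(zip_path: Path) -> Category | None:
    """Parse the combined barcodes+metadata member of an HCA matrix zip.

    Header-driven: the first column is the cell barcode; every later
    column becomes a CategoryRow.  Returns None when no such member exists
    (barcodes-only archives).
    """
    with zipfile.ZipFile(zip_path) as zf:
        candidates = [n for n in zf.namelist()
                      if n.rsplit("/", 1)[-1].endswith((".csv", ".tsv"))
                      and ("cell" in n.lower() or "barcode" in n.lower())]
        member = None
        for name in candidates:
            text = zf.read(name).decode("utf-8", errors="replace")
            header = text.splitlines()[0] if text.strip() else ""
            n_cols = len(header.split("\t" if "\t" in header else ","))
            if n_cols >= 2:
                member = name
                break
        if member is None:
            return None
        with tempfile.NamedTemporaryFile("wb", suffix=".csv", delete=False) as fh:
            fh.write(zf.read(member))
            tmp_name = fh.name
    try:
        return read_category_csv(tmp_name, transpose=True, name="Cell metadata")
    except FormatError:
        return None
    finally:
        Path(tmp_name).unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# Fixture stores
# ---------------------------------------------------------------------------


def gxa_fixture_payloads(
    exp: ExpressionExperiment, category: Category
) -> dict[str, bytes]:
    """Build a recorded-payload mapping serving ``exp`` as a GXA accession.

    The returned dict maps the exact endpoint URLs (listing, matrix zip,
    clusters, experiment design) to byte payloads in the shapes the live
    service ships, suitable for :class:`FixtureTransport`.
    """
    from .matrix_io import write_clusters_csv, write_mtx_triple

    accession = exp.accession or "SYN-0001"
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        triple = write_mtx_triple(exp, tmpdir, stem=accession)
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
            for p in triple:
                zf.write(p, arcname=p.name)
        matrix_zip = buf.getvalue()
        clusters_path = tmpdir / "clusters.csv"
        write_clusters_csv(category, clusters_path, cell_ids=exp.cell_ids)
        clusters_bytes = clusters_path.read_bytes()

    design_lines = ["cell_id\tspecies"]
    design_lines += [f"{c}\t{exp.species or 'unknown'}" for c in exp.cell_ids]
    design_bytes = ("\n".join(design_lines) + "\n").encode()

    listing = {"experiments": [{
        "experimentAccession": accession,
        "experimentDescription": "synthetic fixture experiment",
        "species": exp.species,
        "numberOfAssays": exp.n_cells,
    }]}
    return {
        GXA_EXPERIMENTS_URL: json.dumps(listing).encode(),
        GXA_MATRIX_URL % accession: matrix_zip,
        GXA_CLUSTERS_URL % accession: clusters_bytes,
        GXA_DESIGN_URL % accession: design_bytes,
    }
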