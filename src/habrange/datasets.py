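"""Bundled occurrence data.

The package ships the seven known collection sites of the Corsican
endemic blow fly *Nesodexia corsicana* (Calliphoridae: Rhinophorinae),
transcribed from published collection labels.  Six sites carry printed
coordinates (a mix of DMS and decimal forms); the 1907 type locality
("Campo di Loro") has none and is georeferenced by default to the Campo
dell'Oro plain near Ajaccio (41.93° N, 8.79° E) — a choice the extent
of occurrence is sensitive to, so it can be overridden.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_occurrences
from .range_metrics import OccurrenceRecord

__all__ = ["corsica_occurrences", "corsica_occurrences_path"]


def corsica_occurrences_path() -> Path:
    """Filesystem path of the bundled occurrence CSV."""
    return Path(resources.files("habrange").joinpath("data/nesodexia_corsicana.csv"))


def corsica_occurrences(
    type_locality_lon: float | None = None,
    type_locality_lat: float | None = None,
) -> list[OccurrenceRecord]:
    """The seven *N. corsicana* occurrence records.

    Pass ``type_locality_lon``/``type_locality_lat`` to override the
    default gazetteer georeference of the 1907 type locality.
    """
    records = read_occurrences(corsica_occurrences_path())
    if type_locality_lon is not None or type_locality_lat is not None:
        out = []
        for r in records:
            if r.id == "campo-di-loro":
                r = OccurrenceRecord(
                    id=r.id,
                    lon=type_locality_lon if type_locality_lon is not None else r.lon,
                    lat=type_locality_lat if type_locality_lat is not None else r.lat,
                    year=r.year,
                    elevation_m=r.elevation_m,
                    georeference_note=r.georeference_note + "; overridden",
                )
            out.append(r)
        records = out
    return records
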