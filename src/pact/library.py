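"""Reference library of registered limb-socket pairs.

A :class:`Library` holds one :class:`LibraryEntry` per participant: the
anatomically aligned limb mesh with its landmarks, the socket registered in
the same frame, and participant metadata.  Persistence is a diff-able JSON
manifest plus one PLY file per mesh and one JSON sidecar per landmark set.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .anatomy import LandmarkSet
from .errors import LibraryError, InputError
from .mesh_core import load_mesh

__all__ = [
    "ParticipantMeta",
    "LibraryEntry",
    "Library",
    "build_library",
    "leave_one_out",
    "summarize",
]

LENGTH_CLASSES = ("long", "short", "very_short")
SHAPE_CLASSES = ("conical", "cylindrical", "bulbous")

#: tolerance between stated limb length and the aligned mesh z-extent, mm
_LENGTH_TOL = 1.0


@dataclass
class ParticipantMeta:
    id: str
    sex: str
    age: float
    limb_length: float
    length_class: str
    shape_class: str

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise InputError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.age > 0:
            raise InputError("age must be positive")
        if not self.limb_length > 0:
            raise InputError("limb_length must be positive")
        if self.length_class not in LENGTH_CLASSES:
            raise InputError(f"length_class must be one of {LENGTH_CLASSES}")
        if self.shape_class not in SHAPE_CLASSES:
            raise InputError(f"shape_class must be one of {SHAPE_CLASSES}")

    def to_dict(self) -> dict:
        return {
            "id": self.id, "sex": self.sex, "age": self.age,
            "limb_length": self.limb_length,
            "length_class": self.length_class, "shape_class": self.shape_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantMeta":
        return cls(**{k: d[k] for k in (
            "id", "sex", "age", "limb_length", "length_class", "shape_class")})


@dataclass
class LibraryEntry:
    """One registered limb-socket pair; limb and socket share one frame."""

    meta: ParticipantMeta
    limb: trimesh.Trimesh
    landmarks: LandmarkSet
    socket: trimesh.Trimesh

    def validate(self) -> None:
        z_extent = float(np.ptp(np.asarray(self.limb.vertices)[:, 2]))
        if abs(z_extent - self.meta.limb_length) > _LENGTH_TOL:
            raise LibraryError(
                f"entry {self.meta.id}: limb_length {self.meta.limb_length:.1f} mm "
                f"disagrees with mesh z-extent {z_extent:.1f} mm"
            )

    @property
    def limb_length(self) -> float:
        return self.meta.limb_length


class Library:
    """Keyed, validated collection of limb-socket pairs."""

    def __init__(self, entries: dict[str, LibraryEntry]):
        if not entries:
            raise LibraryError("library must contain at least one entry")
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pid: str) -> bool:
        return pid in self._entries

    def __getitem__(self, pid: str) -> LibraryEntry:
        try:
            return self._entries[pid]
        except KeyError:
            raise KeyError(f"no participant {pid!r} in library") from None

    def __iter__(self):
        return iter(self.ids)

    @property
    def ids(self) -> list[str]:
        return sorted(self._entries)

    @property
    def entries(self) -> list[LibraryEntry]:
        return [self._entries[i] for i in self.ids]

    def leave_one_out(self, pid: str) -> "Library":
        """New library without ``pid``; this library is untouched."""
        if pid not in self._entries:
            raise KeyError(f"no participant {pid!r} in library")
        if len(self._entries) < 2:
            raise LibraryError("cannot leave one out of a single-entry library")
        remaining = {k: v for k, v in self._entries.items() if k != pid}
        return Library(remaining)

    def summarize(self) -> pd.DataFrame:
        """Per-entry metadata table with Average / Std. Dev. footer rows.

        SD is the sample (n-1) estimator; for a single entry it is NA.
        """
        rows = [e.meta.to_dict() for e in self.entries]
        df = pd.DataFrame(rows)
        footer = {
            "id": ["Average", "Std. Dev."],
            "age": [df["age"].mean(),
                    df["age"].std(ddof=1) if len(df) > 1 else np.nan],
            "limb_length": [df["limb_length"].mean(),
                            df["limb_length"].std(ddof=1) if len(df) > 1 else np.nan],
        }
        return pd.concat([df, pd.DataFrame(footer)], ignore_index=True)

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | os.PathLike) -> str:
        """Write manifest.json plus per-entry PLY meshes and landmark JSON.

        PLY stores single-precision coordinates, so a first save quantizes
        vertices to float32; save -> load -> save is bitwise stable.
        """
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        manifest = {"entries": []}
        for entry in self.entries:
            pid = entry.meta.id
            limb_path = f"{pid}_limb.ply"
            socket_path = f"{pid}_socket.ply"
            lm_path = f"{pid}_limb.landmarks.json"
            entry.limb.export(os.path.join(directory, limb_path))
            entry.socket.export(os.path.join(directory, socket_path))
            entry.landmarks.to_json(os.path.join(directory, lm_path))
            manifest["entries"].append({
                "meta": entry.meta.to_dict(),
                "limb": limb_path,
                "socket": socket_path,
                "landmarks": lm_path,
            })
        manifest_path = os.path.join(directory, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest_path

    @classmethod
    def load(cls, manifest_path: str | os.PathLike) -> "Library":
        manifest_path = os.fspath(manifest_path)
        if os.path.isdir(manifest_path):
            manifest_path = os.path.join(manifest_path, "manifest.json")
        base = os.path.dirname(manifest_path)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        entries = []
        for item in manifest["entries"]:
            meta = ParticipantMeta.from_dict(item["meta"])
            limb = load_mesh(os.path.join(base, item["limb"]))
            socket = load_mesh(os.path.join(base, item["socket"]))
            landmarks = LandmarkSet.from_json(os.path.join(base, item["landmarks"]))
            entries.append(LibraryEntry(meta=meta, limb=limb,
                                        landmarks=landmarks, socket=socket))
        return build_library(entries)


def build_library(entries: list[LibraryEntry]) -> Library:
    """Validate entries (unique ids, length/extent agreement) into a Library."""
    if not entries:
        raise LibraryError("cannot build a library from an empty entry list")
    keyed: dict[str, LibraryEntry] = {}
    for entry in entries:
        pid = entry.meta.id
        if pid in keyed:
            raise LibraryError(f"duplicate participant id {pid!r}")
        entry.validate()
        keyed[pid] = entry
    return Library(keyed)


def leave_one_out(lib: Library, pid: str) -> Library:
    """Functional alias for :meth:`Library.leave_one_out`."""
    return lib.leave_one_out(pid)


def summarize(lib: Library) -> pd.DataFrame:
    """Functional alias for :meth:`Library.summarize`."""
    return lib.summarize()
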