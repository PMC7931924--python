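"""Post corpora: the canonical record schema, JSONL/CSV round-trips, and
replay of archived liveticker JSON documents.

A liveticker is a live-updating stream of small news items, each carrying its
own comment thread; archived documents are flattened into the flat post schema
with ``item_id`` linking each post to its parent item. HTTP retrieval is out
of scope — this module only replays documents already on disk.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Post", "Corpus", "read_posts", "write_posts", "flatten_liveticker_json", "load_liveticker_fixture"]

_CSV_COLUMNS = ["id", "platform", "timestamp", "user_id", "item_id", "text"]
_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class Post:
    """One timestamped text record from a platform.

    ``text`` may be empty (it scores as zero tokens) but never absent;
    ``user_id`` is optional because some platforms are anonymous; ``item_id``
    is the liveticker small-news item the post sits under, where applicable.
    """

    id: str
    platform: str
    timestamp: datetime
    text: str
    user_id: str | None = None
    item_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("post id must be non-empty")
        if not isinstance(self.timestamp, datetime) or self.timestamp.tzinfo is None:
            raise ValueError(f"post {self.id!r}: timestamp must be timezone-aware")
        if self.text is None:
            raise ValueError(f"post {self.id!r}: text may be empty but not absent")


@dataclass(frozen=True)
class Corpus:
    posts: tuple[Post, ...]
    platform: str
    period: tuple[datetime, datetime]

    def __post_init__(self) -> None:
        ids = set()
        lo, hi = self.period
        for p in self.posts:
            if p.platform != self.platform:
                raise ValueError(f"post {p.id!r} platform {p.platform!r} != corpus platform {self.platform!r}")
            if p.id in ids:
                raise ValueError(f"duplicate post id {p.id!r}")
            ids.add(p.id)
            if not (lo <= p.timestamp <= hi):
                raise ValueError(f"post {p.id!r} timestamp outside corpus period")

    def __len__(self) -> int:
        return len(self.posts)

    @classmethod
    def from_posts(cls, posts: Sequence[Post], platform: str | None = None) -> "Corpus":
        posts = tuple(posts)
        if not posts:
            raise ValueError("cannot build a corpus from zero posts")
        if platform is None:
            platform = posts[0].platform
        times = [p.timestamp for p in posts]
        return cls(posts, platform, (min(times), max(times)))


# --------------------------------------------------------------------------- #
# readers / writers


def _post_from_record(rec: dict[str, Any]) -> Post:
    ts = rec["timestamp"]
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts.replace("Z", "+00:00"))
    return Post(
        id=str(rec["id"]),
        platform=str(rec["platform"]),
        timestamp=ts,
        text=rec["text"],
        user_id=rec.get("user_id") or None,
        item_id=rec.get("item_id") or None,
    )


def read_posts(path: str | Path, format: str | None = None) -> Corpus:
    """Read a post corpus from JSONL (one object per line) or CSV.

    Records failing validation (missing fields, naive timestamps) are skipped
    with a logged count; more than 50% invalid records raises, since that
    usually means the wrong schema was supplied.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    records: list[dict[str, Any]]
    if format == "jsonl":
        records = []
        with open(path, encoding="utf-8") as fh:
            for ln in fh:
                ln = ln.strip()
                if ln:
                    records.append(json.loads(ln))
    elif format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({"": None})
        records = df.to_dict("records")
    else:
        raise ValueError(f"unknown format {format!r}")

    posts: list[Post] = []
    bad = 0
    for rec in records:
        try:
            if rec.get("text") is None:
                rec = dict(rec)
                rec["text"] = "" if "text" in rec else None
            posts.append(_post_from_record(rec))
        except (KeyError, TypeError, ValueError) as exc:
            bad += 1
            logger.debug("skipping invalid record: %s", exc)
    if bad:
        logger.warning("skipped %d invalid record(s) out of %d in %s", bad, len(records), path)
    if records and bad > len(records) / 2:
        raise ValueError(f"{bad}/{len(records)} records invalid — wrong schema for {path}?")
    return Corpus.from_posts(posts)


def write_posts(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus so that :func:`read_posts` round-trips it losslessly."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for p in corpus.posts:
                rec = {
                    "id": p.id,
                    "platform": p.platform,
                    "timestamp": p.timestamp.isoformat(),
                    "user_id": p.user_id,
                    "item_id": p.item_id,
                    "text": p.text,
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "csv":
        rows = [
            {
                "id": p.id,
                "platform": p.platform,
                "timestamp": p.timestamp.isoformat(),
                "user_id": p.user_id or "",
                "item_id": p.item_id or "",
                "text": p.text,
            }
            for p in corpus.posts
        ]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# --------------------------------------------------------------------------- #
# liveticker replay


def flatten_liveticker_json(
    doc: dict[str, Any], platform: str = "derstandard"
) -> tuple[list[str], list[Post]]:
    """Flatten an archived liveticker document into (item ids, posts).

    Expected replay schema (the archive's own contract, shipped with a fixture
    under ``data/``)::

        {"liveticker_id": ..., "items": [
            {"id": ..., "timestamp": ..., "posts": [
                {"id": ..., "author": ..., "timestamp": ..., "text": ...}, ...]}, ...]}

    Item order is preserved; posts appearing in several batch documents for the
    same item are de-duplicated by post id. Idempotent on already-flat input.
    """
    items = doc.get("items")
    if not isinstance(items, list):
        raise ValueError("liveticker document has no 'items' array")
    item_ids: list[str] = []
    posts: list[Post] = []
    seen: set[str] = set()
    for j, item in enumerate(items):
        iid = item.get("id")
        if not iid:
            raise ValueError(f"items[{j}]: missing item id")
        item_ids.append(str(iid))
        raw_posts = item.get("posts", [])
        if not isinstance(raw_posts, list):
            raise ValueError(f"items[{j}] ({iid}): 'posts' is not an array")
        for rp in raw_posts:
            pid = str(rp["id"])
            if pid in seen:
                continue
            seen.add(pid)
            posts.append(
                Post(
                    id=pid,
                    platform=platform,
                    timestamp=datetime.fromisoformat(rp["timestamp"]),
                    text=rp.get("text", ""),
                    user_id=rp.get("author") or None,
                    item_id=str(iid),
                )
            )
    logger.info("flattened %d items into %d posts", len(item_ids), len(posts))
    return item_ids, posts


def load_liveticker_fixture() -> dict[str, Any]:
    with open(_DATA_DIR / "liveticker_fixture.json", encoding="utf-8") as fh:
        return json.load(fh)
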