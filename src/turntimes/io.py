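"""Readers and writers for the package's plain-text interchange formats.

* RT CSV: ``participant_id, display, response, rt_ms, correct``
* Corpus CSV: ``conversation_id, group_size, speaker_id, onset_ms,
  offset_ms, labels`` (labels semicolon-separated vocabulary terms)
* Praat TextGrid (long text format, interval tiers): one tier per speaker,
  non-empty interval text = vocalization; annotation labels ride in a
  sidecar CSV keyed by tier name + interval index.
* Transitions TSV: one row per measured transition.

Times are serialized as milliseconds with at most 3 decimal places.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Union

import pandas as pd

from turntimes.synthetic import DISPLAYS, RESPONSES
from turntimes.transitions import Transition, transitions_to_frame
from turntimes.types import Conversation, Corpus, Turn, check_vocabulary

PathLike = Union[str, Path]

RT_COLUMNS = ["participant_id", "display", "response", "rt_ms", "correct"]
CORPUS_COLUMNS = [
    "conversation_id", "group_size", "speaker_id", "onset_ms", "offset_ms",
    "labels",
]


# --------------------------------------------------------------------------
# RT CSV
# --------------------------------------------------------------------------

def read_rt_csv(path: PathLike) -> pd.DataFrame:
    """Read an RT CSV, validating schema and vocabulary row by row."""
    df = pd.read_csv(path)
    missing = set(RT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = df.index[rt.isna()]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: non-numeric rt_ms on line {bad[0] + 2}")
    df["rt_ms"] = rt.astype(float)
    bad_disp = df.index[~df["display"].isin(DISPLAYS)]
    if len(bad_disp):
        raise ValueError(
            f"{path}: unknown display label "
            f"{df.loc[bad_disp[0], 'display']!r} on line {bad_disp[0] + 2}"
        )
    bad_resp = df.index[~df["response"].isin(RESPONSES)]
    if len(bad_resp):
        raise ValueError(
            f"{path}: unknown response label "
            f"{df.loc[bad_resp[0], 'response']!r} on line {bad_resp[0] + 2}"
        )
    df["correct"] = df["correct"].astype(bool)
    return df[RT_COLUMNS]


def write_rt_csv(dataset: pd.DataFrame, path: PathLike) -> None:
    out = dataset[RT_COLUMNS].copy()
    out["rt_ms"] = out["rt_ms"].round(3)
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Corpus CSV
# --------------------------------------------------------------------------

def write_corpus_csv(corpus: Corpus, path: PathLike) -> None:
    rows = []
    for conv in corpus:
        for t in conv.turns:
            rows.append(
                {
                    "conversation_id": conv.conversation_id,
                    "group_size": conv.group_size,
                    "speaker_id": t.speaker_id,
                    "onset_ms": round(t.onset_ms, 3),
                    "offset_ms": round(t.offset_ms, 3),
                    "labels": ";".join(sorted(t.labels)),
                }
            )
    pd.DataFrame(rows, columns=CORPUS_COLUMNS).to_csv(path, index=False)


def read_corpus_csv(path: PathLike) -> Corpus:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(CORPUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    conversations = []
    for (conv_id, group_size), grp in df.groupby(
        ["conversation_id", "group_size"], sort=True
    ):
        turns = [
            Turn(
                conversation_id=str(conv_id),
                speaker_id=str(r.speaker_id),
                onset_ms=float(r.onset_ms),
                offset_ms=float(r.offset_ms),
                labels=check_vocabulary(
                    [s for s in str(r.labels).split(";") if s]
                ),
            )
            for r in grp.itertuples()
        ]
        conversations.append(
            Conversation(
                conversation_id=str(conv_id),
                group_size=int(group_size),
                turns=turns,
            )
        )
    return Corpus(conversations)


# --------------------------------------------------------------------------
# Praat TextGrid (long text format, interval tiers)
# --------------------------------------------------------------------------

def write_textgrid(
    conversation: Conversation, path: PathLike, sidecar: PathLike | None = None
) -> None:
    """Write one conversation as a TextGrid with one interval tier per speaker.

    Non-empty interval text marks a vocalization.  Times are seconds in the
    file, milliseconds in memory.  If ``sidecar`` is given, labels are
    written there keyed by (tier, interval_index).
    """
    xmax = max(t.offset_ms for t in conversation.turns) / 1000.0
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {conversation.group_size}",
        "item []:",
    ]
    sidecar_rows = []
    for ti, speaker in enumerate(conversation.speakers, start=1):
        turns = [t for t in conversation.turns if t.speaker_id == speaker]
        # build intervals: alternate silence / speech covering [0, xmax]
        intervals: list[tuple[float, float, str]] = []
        cursor = 0.0
        for t in turns:
            a, b = t.onset_ms / 1000.0, t.offset_ms / 1000.0
            if a > cursor:
                intervals.append((cursor, a, ""))
            intervals.append((a, b, "speech"))
            cursor = b
        if cursor < xmax:
            intervals.append((cursor, xmax, ""))
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{speaker}"',
            "        xmin = 0",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(intervals)}",
        ]
        speech_idx = 0
        for ii, (a, b, text) in enumerate(intervals, start=1):
            lines += [
                f"        intervals [{ii}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{text}"',
            ]
            if text:
                labels = sorted(turns[speech_idx].labels)
                if labels:
                    sidecar_rows.append(
                        {
                            "tier": speaker,
                            "interval_index": ii,
                            "labels": ";".join(labels),
                        }
                    )
                speech_idx += 1
    Path(path).write_text("\n".join(lines) + "\n")
    if sidecar is not None:
        pd.DataFrame(
            sidecar_rows, columns=["tier", "interval_index", "labels"]
        ).to_csv(sidecar, index=False)


_TG_FLOAT = re.compile(r"=\s*([-\d.eE+]+)")
_TG_STRING = re.compile(r'=\s*"(.*)"')


def read_textgrid(
    path: PathLike,
    conversation_id: str | None = None,
    sidecar: PathLike | None = None,
) -> Conversation:
    """Read an interval-tier TextGrid as one conversation.

    Each tier is a speaker; intervals with non-empty text are vocalizations.
    Overlapping intervals within one tier are an error.  Labels, if any,
    come from the sidecar CSV keyed by tier name + interval index.
    """
    text = Path(path).read_text()
    if "IntervalTier" not in text:
        raise ValueError(f"{path}: no interval tiers found")

    label_map: dict[tuple[str, int], frozenset[str]] = {}
    if sidecar is not None:
        sc = pd.read_csv(sidecar, keep_default_na=False)
        for r in sc.itertuples():
            label_map[(str(r.tier), int(r.interval_index))] = check_vocabulary(
                [s for s in str(r.labels).split(";") if s]
            )

    turns: list[Turn] = []
    conv_id = conversation_id or Path(path).stem
    tier_name = None
    interval_idx = 0
    xmin = xmax = None
    n_tiers = 0
    lines = iter(text.splitlines())
    for line in lines:
        s = line.strip()
        if s.startswith("name ="):
            m = _TG_STRING.search(s)
            tier_name = m.group(1) if m else None
            n_tiers += 1
            interval_idx = 0
            last_offset = -float("inf")
        elif s.startswith("intervals ["):
            interval_idx += 1
            xmin = xmax = None
        elif s.startswith("xmin =") and tier_name and interval_idx:
            xmin = float(_TG_FLOAT.search(s).group(1))
        elif s.startswith("xmax =") and tier_name and interval_idx:
            xmax = float(_TG_FLOAT.search(s).group(1))
        elif s.startswith("text =") and tier_name and interval_idx:
            content = _TG_STRING.search(s).group(1)
            if content.strip():
                onset, offset = xmin * 1000.0, xmax * 1000.0
                if onset < last_offset:
                    raise ValueError(
                        f"{path}: overlapping intervals in tier {tier_name!r}"
                    )
                last_offset = offset
                turns.append(
                    Turn(
                        conversation_id=conv_id,
                        speaker_id=tier_name,
                        onset_ms=onset,
                        offset_ms=offset,
                        labels=label_map.get(
                            (tier_name, interval_idx), frozenset()
                        ),
                    )
                )
    if n_tiers == 0:
        raise ValueError(f"{path}: empty tier set")
    group_size = len({t.speaker_id for t in turns})
    return Conversation(
        conversation_id=conv_id, group_size=group_size, turns=turns
    )


def read_corpus(path: PathLike, format: str = "csv", **kwargs) -> Corpus:
    """Read a corpus from CSV (many conversations) or TextGrid (one)."""
    if format == "csv":
        return read_corpus_csv(path)
    if format == "textgrid":
        return Corpus([read_textgrid(path, **kwargs)])
    raise ValueError("format must be 'csv' or 'textgrid'")


# --------------------------------------------------------------------------
# Transitions TSV
# --------------------------------------------------------------------------

def write_transitions_tsv(
    transitions: list[Transition], path: PathLike
) -> None:
    frame = transitions_to_frame(transitions)
    frame["transition_ms"] = frame["transition_ms"].round(3)
    frame["excluded_reason"] = frame["excluded_reason"].fillna("")
    frame.to_csv(path, sep="\t", index=False)


def read_transitions_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["transition_ms"] = df["transition_ms"].astype(float)
    df["group_size"] = df["group_size"].astype(int)
    df["overlap"] = df["overlap"].astype(str).str.lower().isin(
        ("true", "1")
    )
    df["excluded_reason"] = df["excluded_reason"].replace("", pd.NA)
    return df
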