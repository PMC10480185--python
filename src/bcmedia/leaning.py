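"""Hashtag-based leaning construction for the case-study pipeline.

Annotated hashtags carry alignment scores in {-3, -1, 0, +1, +3} (0 = neutral or
irrelevant). A tweet's value C_t is the mean of its non-neutral hashtag scores;
a user's value C_u is the mean of their defined tweet values. C_u in [-3, 3] is
mapped linearly to an opinion on [0, 1] and discretized into Pro / Neutral /
Against. Faction-average opinions serve as media landscapes for simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MediaLandscape

__all__ = [
    "ALLOWED_SCORES",
    "tweet_value",
    "user_value",
    "normalize_leaning",
    "denormalize_leaning",
    "discretize_leaning",
    "user_leanings",
    "faction_media_opinions",
    "synthetic_annotations",
]

logger = logging.getLogger(__name__)

ALLOWED_SCORES = {-3, -1, 0, 1, 3}
PRO_THRESHOLD = 0.4  # normalized opinion <= 0.4 -> Pro
AGAINST_THRESHOLD = 0.6  # normalized opinion >= 0.6 -> Against


def _check_scores(values: Iterable[int]) -> list[int]:
    out = []
    for v in values:
        iv = int(v)
        if iv != v or iv not in ALLOWED_SCORES:
            raise ValueError(f"hashtag score {v!r} not in {sorted(ALLOWED_SCORES)}")
        out.append(iv)
    return out


def tweet_value(hashtag_scores: Iterable[int]) -> float | None:
    """Mean of the non-neutral hashtag scores of one tweet (C_t); ``None`` when
    the tweet carries only neutral hashtags (such tweets are excluded)."""
    scores = [v for v in _check_scores(hashtag_scores) if v != 0]
    if not scores:
        return None
    return float(np.mean(scores))


def user_value(tweet_values: Iterable[float | None]) -> float:
    """Mean of a user's defined tweet values (C_u, in [-3, 3])."""
    defined = [v for v in tweet_values if v is not None]
    if not defined:
        raise ValueError("user has no tweets with non-neutral hashtags")
    return float(np.mean(defined))


def normalize_leaning(c_u: float) -> float:
    """Linear map of C_u in [-3, 3] onto [0, 1] (-3 -> 0, 0 -> 0.5, +3 -> 1)."""
    if not -3.0 <= c_u <= 3.0:
        raise ValueError(f"C_u must lie in [-3, 3], got {c_u}")
    return (c_u + 3.0) / 6.0


def denormalize_leaning(opinion: float) -> float:
    """Exact inverse of :func:`normalize_leaning`: ``C_u = 6*opinion - 3``."""
    if not 0.0 <= opinion <= 1.0:
        raise ValueError(f"opinion must lie in [0, 1], got {opinion}")
    return 6.0 * opinion - 3.0


def discretize_leaning(opinion: float) -> str:
    """Three-way label on the normalized scale: Pro (<= 0.4), Against (>= 0.6),
    Neutral otherwise."""
    if not 0.0 <= opinion <= 1.0:
        raise ValueError(f"opinion must lie in [0, 1], got {opinion}")
    if opinion <= PRO_THRESHOLD:
        return "Pro"
    if opinion >= AGAINST_THRESHOLD:
        return "Against"
    return "Neutral"


def user_leanings(annotations: pd.DataFrame) -> pd.DataFrame:
    """Full pipeline: annotation table -> one leaning record per scorable user.

    ``annotations`` needs columns ``tweet_id``, ``user_id``, ``hashtag``,
    ``class_value``. Tweets with only neutral hashtags are dropped, then users
    with no remaining tweets are excluded (counted in a log message). Returns a
    frame with columns ``user_id, c_u, opinion, label`` sorted by user id.
    """
    required = {"tweet_id", "user_id", "hashtag", "class_value"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table is missing columns: {sorted(missing)}")
    _check_scores(annotations["class_value"])

    nonneutral = annotations[annotations["class_value"] != 0]
    c_t = (
        nonneutral.groupby(["user_id", "tweet_id"])["class_value"]
        .mean()
        .rename("c_t")
        .reset_index()
    )
    n_users_total = annotations["user_id"].nunique()
    c_u = c_t.groupby("user_id")["c_t"].mean().rename("c_u").reset_index()
    excluded = n_users_total - len(c_u)
    if excluded:
        logger.info("excluded %d user(s) with no non-neutral tweets", excluded)
    c_u["opinion"] = (c_u["c_u"] + 3.0) / 6.0
    c_u["label"] = c_u["opinion"].map(discretize_leaning)
    return c_u.sort_values("user_id").reset_index(drop=True)


def faction_media_opinions(
    opinions: Sequence[float], labels: Sequence[str]
) -> MediaLandscape:
    """Faction-average opinions as a media landscape, ordered Pro, Neutral,
    Against; empty factions are omitted with a log message."""
    opinions = np.asarray(opinions, dtype=np.float64)
    labels = np.asarray(labels)
    if opinions.size != labels.size:
        raise ValueError("opinions and labels must have matching lengths")
    means = []
    for faction in ("Pro", "Neutral", "Against"):
        mask = labels == faction
        if mask.any():
            means.append(float(opinions[mask].mean()))
        else:
            logger.warning("faction %s is empty; its medium is omitted", faction)
    return MediaLandscape(tuple(means))


def synthetic_annotations(
    n_users: int,
    rng: np.random.Generator,
    tweets_per_user: int = 3,
    hashtags_per_tweet: int = 2,
    faction_weights: tuple[float, float, float] = (0.45, 0.1, 0.45),
    neutral_rate: float = 0.2,
) -> pd.DataFrame:
    """Seeded synthetic annotation table for tests and examples.

    Users are assigned to Pro / Neutral / Against factions with the given
    weights; their hashtags are drawn to lean accordingly (Pro towards negative
    scores, Against towards positive ones), with ``neutral_rate`` of hashtags
    scored 0.
    """
    if n_users < 1:
        raise ValueError("need at least one user")
    rows = []
    factions = rng.choice(3, size=n_users, p=np.asarray(faction_weights) / np.sum(faction_weights))
    # score distributions per faction over (-3, -1, 1, 3)
    profiles = {
        0: (0.6, 0.3, 0.07, 0.03),  # Pro
        1: (0.2, 0.3, 0.3, 0.2),  # Neutral
        2: (0.03, 0.07, 0.3, 0.6),  # Against
    }
    tweet_id = 0
    for u in range(n_users):
        probs = np.asarray(profiles[int(factions[u])], dtype=np.float64)
        for _ in range(tweets_per_user):
            for _ in range(hashtags_per_tweet):
                if rng.random() < neutral_rate:
                    score = 0
                else:
                    score = int(rng.choice([-3, -1, 1, 3], p=probs))
                rows.append(
                    {
                        "tweet_id": f"t{tweet_id}",
                        "user_id": f"u{u}",
                        "hashtag": f"#tag{rng.integers(50)}",
                        "class_value": score,
                    }
                )
            tweet_id += 1
    return pd.DataFrame(rows)
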