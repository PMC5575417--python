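import random

import pytest

from psychscreen import ClinicalNote, default_lexicon
from psychscreen.lexicon import Lexicon


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return default_lexicon()


def make_note(text: str, patient_id: str = "p1", note_id: str = "n1") -> ClinicalNote:
    return ClinicalNote(patient_id=patient_id, note_id=note_id, text=text)


def brute_force_candidates(tokens: list[str], lexicon: Lexicon) -> list[tuple[int, str]]:
    """Independent oracle: scan every token against every rule directly.

    Operates on a flat token sequence (one sentence); returns (token index,
    term_id) pairs. Deliberately written as plain loops, separate from the
    matcher's code path.
    """
    hits = []
    for j, token in enumerate(tokens):
        for rule in lexicon:
            if rule.case_mode == "exact":
                tok, pat = token, rule.pattern
            else:
                tok, pat = token.lower(), rule.pattern.lower()
            if rule.match_mode == "exact_token":
                ok = tok == pat
            else:
                ok = tok.startswith(pat)
            if not ok:
                continue
            if rule.collocate is not None:
                col = rule.collocate
                found = False
                for k, other in enumerate(tokens):
                    if k == j:
                        continue
                    if other.lower() != col.token.lower():
                        continue
                    if col.direction == "preceding":
                        if j - col.max_distance <= k < j:
                            found = True
                    else:
                        if abs(k - j) <= col.max_distance:
                            found = True
                if not found:
                    continue
            hits.append((j, rule.term_id))
    return hits


#: Vocabulary that stresses the matcher: every lexicon pattern, prefix
#: extensions, near-misses, collocates, cues and neutral filler.
ORACLE_VOCAB = [
    "anxiety", "depressed", "depression", "sad", "sadness", "angry",
    "neurovegetative", "schizoaffective", "substance", "abuse", "abused",
    "addict", "addiction", "AA", "aa", "Aa", "sober", "sobriety", "cocaine",
    "heroin", "crack", "mushrooms", "prison", "jail", "jailed", "jailhouse",
    "homeless", "homelessness", "shelter", "stamps", "stamp", "food",
    "postage", "stolen", "tox", "toxicity", "amino", "acid", "patient",
    "visit", "male", "the", "and", "use", "reports",
]


def random_token_sequences(seed: int, n: int, max_len: int = 12) -> list[list[str]]:
    rng = random.Random(seed)
    return [
        [rng.choice(ORACLE_VOCAB) for _ in range(rng.randint(0, max_len))]
        for _ in range(n)
    ]
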