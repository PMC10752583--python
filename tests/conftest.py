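import numpy as np
import pytest

from songpref import AudioClip, SongModelParams, SongSegmentation, Syllable, generate_song


def make_tone(freq_hz: float, duration_s: float, sample_rate: int = 250_000,
              amplitude: float = 1.0) -> AudioClip:
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    return AudioClip(amplitude * np.sin(2 * np.pi * freq_hz * t), sample_rate)


@pytest.fixture(scope="session")
def small_song():
    """A 30-syllable synthetic song with ground-truth segmentation."""
    clip, seg, gt = generate_song(SongModelParams(n_syllables=30), seed=7)
    return clip, seg, gt


@pytest.fixture()
def toy_segmentation():
    """Two syllables at (0-0.02, 0.12-0.14) s in a 0.3 s song."""
    seg = SongSegmentation(
        (Syllable(0.0, 0.02), Syllable(0.12, 0.14)), duration_s=0.3
    )
    rng = np.random.default_rng(0)
    sr = 250_000
    samples = np.zeros(int(0.3 * sr))
    for s in seg:
        i0, i1 = int(s.onset_s * sr), int(s.offset_s * sr)
        samples[i0:i1] = rng.normal(size=i1 - i0)
    return AudioClip(samples, sr), seg
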