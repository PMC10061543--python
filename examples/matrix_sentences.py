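"""The synthetic matrix-sentence corpus and SNR mixing.

Builds the balanced 100-sentence corpus (each of the 50 words appears
exactly 10 times), renders one sentence, and mixes it with speech-shaped
noise at a requested signal-to-noise ratio.
"""
from collections import Counter

import numpy as np

from cisim import stimuli as st

corpus = st.matrix_corpus(seed=0, n_sentences=100)
counts = Counter(lab for s in corpus for lab in s.labels())
print(f"{len(corpus)} sentences, {len(counts)} distinct words, "
      f"each appearing {set(counts.values())} times")

inv = st.WordInventory()
sentence = corpus[0]
print("first sentence:", " ".join(sentence.labels()))
audio, spans = st.synth_speech(sentence, inv, seed=0)
print(f"audio: {len(audio) / st.FS_HZ:.2f} s at {st.FS_HZ:.0f} Hz, "
      f"level {st.dbfs(audio):.1f} dBFS")

noise = st.speech_shaped_noise(5.0, inv, seed=1)
mix = st.mix_at_snr(audio, noise, snr_db=3.0, seed=2)
sp = st.set_level(audio, -49.0)
res = mix - sp
print(f"mixed at 3 dB SNR: measured "
      f"{20 * np.log10(np.sqrt(np.mean(sp ** 2)) / np.sqrt(np.mean(res ** 2))):.2f} dB")
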