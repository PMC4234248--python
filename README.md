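# fcqual — objective sound quality of frequency-lowered speech

`fcqual` predicts the perceived sound quality of speech processed by
**nonlinear frequency compression (NFC)** — the hearing-aid scheme that
compresses spectral content above a cutoff `F_c` by a ratio CR to restore
audibility of high-frequency cues — and evaluates such predictors against
MUSHRA-style subjective rating tables. It is aimed at hearing researchers
and audio engineers who need a reference-based ("intrusive") quality model
that also handles impaired hearing.

The toolkit contains:

* the NFC processor (`F_out = F_c^{1−p} · F_in^p`, `p = 1/CR`, identity
  below the cutoff) and the two MUSHRA anchors (10th-order 2 kHz
  Butterworth lowpass; hard clipping at 25 % of peak);
* a PEMO auditory front-end — gammatone filterbank, envelope extraction,
  adaptation loops, modulation lowpass (`lp`) or filterbank (`fb`) — with
  a hearing-impairment extension: the audiogram is split per channel into
  inner/outer hair-cell losses (`OHCL = min(0.8·HL, 55 dB)`,
  `IHCL = HL − OHCL`) driving attenuation and instantaneous expansion;
* the quality measures **PSM** (wideband bank, up to 15.3 kHz) and **qc**
  (telephone band, up to 4 kHz): the Pearson correlation of the two
  internal representations, with optional band-importance weighting (±W)
  and asymmetric assimilation (±B);
* the classical LPC-domain distances **ISD, LAR, LLR, WSSD**;
* a correlation harness (Pearson r, Spearman rs; per-talker and
  talker-averaged) and a deterministic synthetic study generator
  (4 talkers × 8 conditions with simulated ratings).

## Worked example

```python
import fcqual as fq

ref = fq.make_speechlike(fq.TALKER_PRESETS["f1"]).at_level(65.0)
conditions = fq.make_condition_set(ref)   # 8 MUSHRA conditions

for label, test in conditions.items():
    score = fq.predict_quality(test, ref, "psm")
    print(f"{label:12s} {score.value:.4f}")
```

prints

```
hidden-ref   1.0000
cr2-fc4k     0.9307
cr2-fc3k     0.8977
cr6-fc3k     0.8505
cr10-fc3k    0.8378
cr2-fc2k     0.8205
lowpass      0.7660
clip         0.9211
```

The hidden reference is scored perfect; quality predictions fall
monotonically with compressor strength (higher CR, lower cutoff), and the
2 kHz lowpass anchor scores worst — the qualitative ordering expected from
listeners. A hearing-impaired variant only needs an audiogram:

```python
import numpy as np
ag = fq.Audiogram(np.array([250, 500, 1000, 2000, 4000, 8000]),
                  np.array([ 20,  30,   40,   55,   70,   80]))
opts = fq.QualityOptions(modulation_mode="lp", audiogram=ag)
fq.predict_quality(conditions["cr2-fc2k"], ref, "psm", opts)
```

From the shell:

```sh
fcqual fixtures --out stim/ --seed 17           # synthetic WAVs + manifest + ratings
fcqual nfc --fc 3000 --cr 6 in.wav out.wav
fcqual anchor --type clip in.wav clip.wav
fcqual quality --measure psm --mod lp ref.wav test.wav
fcqual lpcdist --measure llr ref.wav test.wav
fcqual benchmark --manifest stim/manifest.tsv --ratings stim/ratings.tsv
```

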