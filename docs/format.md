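# The `.gem` event-packet format

A `.gem` file is the concatenation of fixed-size 12-byte packets, one per
metronome window, in tone order. Each packet is:

| bytes | type            | field                                      |
|-------|-----------------|--------------------------------------------|
| 0–3   | uint32, little-endian | tone onset time, integer ms (truncated from the engine's real-valued time) |
| 4–5   | int16, little-endian  | tapper 0 tap time relative to the tone, ms |
| 6–7   | int16, little-endian  | tapper 1 relative tap time, ms             |
| 8–9   | int16, little-endian  | tapper 2 relative tap time, ms             |
| 10–11 | int16, little-endian  | tapper 3 relative tap time, ms             |

Conventions:

- **Missing taps** (no tap registered in the window) are encoded as the
  sentinel **−32768** (the minimum int16), which lies outside any legal
  attribution window. Trials with fewer than four tappers pad the unused
  trailing slots with the same sentinel.
- A valid non-sentinel relative tap lies within ± half the nominal IOI
  (e.g. [−250, 250) ms at the default 500 ms IOI).
- Byte order is little-endian throughout (the AVR/Arduino convention).
- A file of *n* windows is exactly 12 *n* bytes; a length not divisible by
  12 is a truncation error, reported with the byte offset of the partial
  packet.
- Tone onsets must be strictly increasing; readers warn on violations.

An optional JSON **sidecar** named `<file>.gem.json` carries the trial
configuration (IOI, alpha, tone count, tapper count, feedback tag, start
time) and the seed provenance. Without a sidecar, readers assume four
tapper slots and infer the IOI from the first inter-tone gap (which is
always the nominal IOI, since adaptation starts only at the third tone).

## Tidy CSV layout

The equivalent flat layout has one row per window per tapper with the
columns

    trial_id, alpha, tone_index, tone_time, tapper_id, tap_rel, missed

where a missing tap renders as an empty `tap_rel` cell with `missed = 1`.
The binary↔CSV round trip is lossless for integer-millisecond data.
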