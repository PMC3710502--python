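# CSV dialect grammar

Common rules for both families:

- separator: `,` (comma) only; no quoting, no escaping
- leading/trailing whitespace around each field is trimmed
- no header row
- decimal point is `.`; scientific notation accepted on read
- line endings: LF or CRLF; blank trailing lines ignored
- the CSV dialect cannot express dataset names, the chain flag, layer
  names or class labels — writers emit a `LOSSY_CSV` warning for each
  dropped field

## Dataset family

```
file  := line+
line  := number "," number "," number
```

One point per line, in display order. Exactly three numeric fields per
line (`BAD_ARITY` otherwise); each must be a finite real
(`BAD_COORDINATE` otherwise). Parsed datasets get the documented default
name `unnamed` and `chain = false`.

## Information family

```
file  := row+
row   := int ("," int)*
```

One row per point, one column per layer; all rows must have the same
number of columns (`RAGGED_LAYERS` otherwise) and every field must be an
integer (`VALUE_OUT_OF_RANGE` otherwise). Each column's `numClass` is
inferred as its count of distinct values; the sorted distinct ids are
rank-mapped onto `0..numClass-1` (warning `ONE_BASED_NORMALISED` when
they were exactly `1..numClass`, `REMAPPED_VALUES` for any other
non-canonical ids).

## Family ambiguity

A CSV with exactly three all-integer columns is valid under both
grammars and is rejected as `AMBIGUOUS_CSV_FAMILY`; callers must state
the family explicitly.
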