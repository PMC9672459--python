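# Six B-DNA local structural parameters per dinucleotide step, compiled from
# crystallographic literature averages (approximate values; units: degrees for
# twist/tilt/roll, Angstrom for shift/slide/rise). All pseudo-composition and
# covariance encoders standardize each index to mean 0 / population SD 1 over
# the 16 dinucleotides before use, so only the relative structure matters.
dinucleotide	twist	tilt	roll	shift	slide	rise
AA	35.6	-1.4	0.7	-0.03	-0.08	3.27
AC	34.4	-0.1	0.7	0.13	-0.58	3.36
AG	27.7	-1.7	4.5	0.09	-0.25	3.34
AT	31.5	0.0	1.1	0.00	-0.59	3.31
CA	34.5	0.5	4.7	0.09	0.53	3.33
CC	33.7	-0.1	3.6	0.05	-0.22	3.42
CG	29.8	0.0	5.4	0.00	0.41	3.39
CT	27.7	1.7	4.5	-0.09	-0.25	3.34
GA	36.9	-1.5	1.9	-0.28	0.09	3.37
GC	40.0	0.0	0.3	0.00	-0.38	3.40
GG	33.7	0.1	3.6	-0.05	-0.22	3.42
GT	34.4	0.1	0.7	-0.13	-0.58	3.36
TA	36.0	0.0	3.3	0.00	0.05	3.42
TC	36.9	1.5	1.9	0.28	0.09	3.37
TG	34.5	-0.5	4.7	-0.09	0.53	3.33
TT	35.6	1.4	0.7	0.03	-0.08	3.27
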