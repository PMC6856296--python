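Transcription notes for the packaged cohort ledgers (table1A.tsv, table1B.tsv)
==============================================================================

The two fixture files transcribe the source study's printed variant tables
(the "highly likely implicated" table and the "uncertain significance" table)
into the printed-layout TSV dialect read by
epicohort.cohort_table.read_ledger(..., dialect="printed").

Normalizations applied during transcription
-------------------------------------------

1. Null markers. The print uses "-", en-dash and blank cells interchangeably
   for "no value"; all are written here as "-" or left blank. The reader
   treats "-", "NA" and the empty string as absent.

2. Corrupted MAF exponents. Several printed MAF cells carry typographically
   corrupted values: either > 1 ("8.1E+00", "1.2E+00") or with impossible
   exponents ("8.9E-106", "1.23E-105", "1.5E-105", "5.4E-105", "9.85E-105",
   "8,2E-106", "4.1E-106", "1.5E-105", "8.9E-106"). These tokens are kept
   verbatim in the fixture; the printed-dialect reader stores them as absent
   and records one normalization note per cell. One value uses a comma
   decimal separator ("8,2E-106"); the reader accepts the comma.

3. Multi-patient row. The recurrent PRRT2 frameshift row lists four patients;
   the print renders the list with inconsistent separators
   ("207 629 975, 1129"). It is transcribed as the comma-separated list
   "207, 629, 975, 1129" and parsed as one record with four patient ids.

4. Gene label "SCN1A-2A". The print labels the 2q24.3 sodium-channel-cluster
   duplication in patient 71 "SCN1A-2A". The study's own gene counts (16
   table-A SCN1A patients, 23 SCN1A variants over both tables, 48 distinct
   genes) attribute this CNV to SCN1A, so the fixture records gene SCN1A;
   the genomic coordinates in the variant column preserve the full span.

5. Reconstructed row (patient "1050"). The machine-extracted text of the
   first table contains 106 rows, yet the study's own totals are explicit:
   107 variants, 104 diagnosed patients, and seven KCNT1 carriers (only six
   appear in the extracted rows). Exactly one row - a KCNT1 record with a
   unique patient - was lost in extraction. It is reconstructed here with
   placeholder patient id "1050" (not otherwise used), gene KCNT1, AD,
   heterozygous, segregation NA, variant type MISS, and all optional fields
   absent; the variant description is the placeholder "c.?". Counts that
   depend on this row: record total (107), distinct patients (104), KCNT1
   patients (7). No score-, MAF- or segregation-dependent statistic is
   affected (segregation NA is excluded from every family-data denominator).

6. Inheritance token "XLR" (patient 1029, GRIA3) parses to XL.
   Segregation token "EN CURSO" (patient 951, DEPDC5) parses to ONGOING.
   Variant-type token "NONFS" (patient 857, ARHGEF15; an in-frame 15-nt
   deletion) parses to INFRAME_INDEL.

7. Continuation rows. Rows with a blank patient cell are additional variants
   of the preceding row's patient(s). Blank INH/ZYG/VFS cells on a
   continuation row inherit the preceding row's value only when the gene is
   unchanged (the print omits repeated cells for same-gene biallelic pairs);
   across a gene change a blank cell stays absent.

8. Patient 860's inheritance cell is blank in print and is kept blank.
   Patient 981's sex cell is blank in print and is kept blank.

9. Cosmetic: "^*^" markup is rendered "*", unicode minus as "-", and
   "p. (" as "p.("; the two renderings of the KCNT1 R262Q protein change
   ("p.R262Q" / "p. R262Q") are unified.
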