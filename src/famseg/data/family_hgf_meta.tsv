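id	generation	alive	genotyped
I-1	1	0	0
I-2	1	0	0
II-1	2	1	1
II-2	2	1	1
II-3	2	1	1
II-4	2	1	1
II-5	2	1	1
II-6	2	1	1
II-7	2	1	1
II-8	2	1	1
II-9	2	1	1
III-1	3	1	1
III-2	3	1	1
III-3	3	1	1
III-4	3	1	1
III-5	3	1	1
III-6	3	1	1
III-7	3	1	1
III-8	3	1	1
III-9	3	1	1
IV-1	4	1	1
IV-2	4	1	1
IV-3	4	1	1
IV-4	4	1	1
IV-5	4	1	1
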