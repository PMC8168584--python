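n_major	n_minor	mcn	timing_class
1	0	0	na
1	0	1	na
1	1	0	na
1	1	1	na
2	0	0	na
2	0	1	late
2	0	2	early
2	1	0	na
2	1	1	na
2	1	2	na
2	2	0	na
2	2	1	late
2	2	2	early
3	0	0	na
3	0	1	late
3	0	2	early
3	0	3	early
3	1	0	na
3	1	1	na
3	1	2	na
3	1	3	na
3	2	0	na
3	2	1	late
3	2	2	early
3	2	3	early
3	3	0	na
3	3	1	late
3	3	2	early
3	3	3	early
4	0	0	na
4	0	1	late
4	0	2	early
4	0	3	early
4	0	4	early
4	1	0	na
4	1	1	na
4	1	2	na
4	1	3	na
4	1	4	na
4	2	0	na
4	2	1	late
4	2	2	early
4	2	3	early
4	2	4	early
4	3	0	na
4	3	1	late
4	3	2	early
4	3	3	early
4	3	4	early
4	4	0	na
4	4	1	late
4	4	2	early
4	4	3	early
4	4	4	early
5	0	0	na
5	0	1	late
5	0	2	early
5	0	3	early
5	0	4	early
5	0	5	early
5	1	0	na
5	1	1	na
5	1	2	na
5	1	3	na
5	1	4	na
5	1	5	na
5	2	0	na
5	2	1	late
5	2	2	early
5	2	3	early
5	2	4	early
5	2	5	early
5	3	0	na
5	3	1	late
5	3	2	early
5	3	3	early
5	3	4	early
5	3	5	early
5	4	0	na
5	4	1	late
5	4	2	early
5	4	3	early
5	4	4	early
5	4	5	early
5	5	0	na
5	5	1	late
5	5	2	early
5	5	3	early
5	5	4	early
5	5	5	early
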