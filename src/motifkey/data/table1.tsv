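motif_id	label	FTN	FN	FT
0000001000011000	4a	76	25	0.329
0000000000011100	4b	48	16	0.333
0000000000001110	4c	16	16	1
0000010000010000000101000	5a	30	8	0.267
0000000000000010000111000	5b	15	6	0.4
0000000000000100100010100	5c	60	14	0.233
000000000000000010000001000001110000	6a	36	8	0.222
000000000000000000000010001000110100	6b	36	14	0.389
000000000000010000000010100000001100	6c	60	12	0.2
000000000000000100000010000001110000	6d	36	14	0.389
000000000000000000000010011000100100	6e	36	8	0.222
000000100000000010000001010000010000	6f	18	8	0.444
000000100000010000000001010000000010	6g	18	8	0.444
000000000000000000000001000001111000	6h	6	6	1
0000000000000000000000000100000001000100001101000	7a	49	18	0.367
0000000000000000000000000000000001000110001100100	7b	21	8	0.381
0000000000000000010000000010000000100000011100000	7c	21	8	0.381
0000000000000000001000000010000000100000011100000	7d	21	8	0.381
0000000100000000000100000001010000001000000000100	7e	21	9	0.429
0000000100000001000000000010010000000000010000100	7f	21	9	0.429
0000000000000000000000000000000000100011001110000	7g	14	8	0.571
0000000000000000000000000001000001000010001110000	7h	14	14	1
0000000000000000000000000001000000100010001110000	7i	14	8	0.571
0000000000000000001000000010100000001000000011000	7j	49	12	0.245
0000000000000000010000000100010000000001001010000	7k	42	10	0.238
0000000000000000000000010000000001011000000001100	7l	42	10	0.238
0000000000000000001000100000000001010000000011000	7m	56	13	0.232
0000000000000000000000010000000001001000001001100	7n	70	12	0.171
0000000000000000010000000100000001001000001010000	7o	50	13	0.26
0000000000000000000000000000001000000010000100000110000010000100	8a	48	10	0.208
0000000000000000000000000000010000000010001000000100000010011000	8b	56	12	0.214
0000000000000000000000000000001010000000000010000110000000010100	8c	48	12	0.25
0000000000000000000000000000000000010000000000100110000010001100	8d	48	10	0.208
0000000000000000000000000010000000000010000010001100000000010100	8e	48	11	0.229
0000000000000000000000000000001000000001000100000110000010000100	8f	48	10	0.208
0000000000000000000100000000100001000000000000100000000110100000	8g	48	11	0.229
0000000000000000000000000000010000100000000000100100000010011000	8h	64	13	0.203
0000000000000000000100000000100000000100000000100100000010100000	8i	48	11	0.229
0000000000000000000100000000100001000000000000100000100010100000	8j	48	11	0.229
0000000000000000000000000000001000100000010000001000000000011100	8k	40	12	0.3
0000000000000000000000000010000000000010100000000100010000011000	8l	32	11	0.344
0000000000000000000000000000100000000100000000100010000011010000	8m	29	13	0.448
0000000000000000000000000000100000000100001000000000000111010000	8n	24	10	0.417
0000000000000000000010000000001000000100000000010000000111000000	8o	24	9	0.375
0000000010000000010000000000010001000000000000100000000100001000	8p	24	10	0.417
0000000000000000000010000000001000010000000000010000000111000000	8q	24	9	0.375
0000000000000000000010000000001000000100000100000000000111000000	8r	24	9	0.375
0000000000000000000000000000100000000100001000000000010011010000	8s	24	10	0.417
0000000010000000000010000000000101000000010000000000010000000010	8t	24	10	0.417
0000000000000000000100000000100000000100010000000100000010100000	8u	16	9	0.563
0000000000000000000100000100000000000001010000000000100010100000	8v	16	9	0.563
0000000000000000000000000000000000000001000100000000110011100000	8w	16	10	0.625
0000000000000000000000000000000000000000000000100011100011000100	8x	8	8	1
0000000000000000000000000000010000000010000000010000000111100000	8y	8	8	1
0000000000000000000000000000100000000010000000010000000111100000	8z	8	8	1
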