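residue,label,hub_score
A:1:,,1
A:2:,,1
A:3:,,1
A:4:,,1
A:5:,,0
A:6:,,54
A:7:,,0
A:8:,,0
A:9:,,4
A:10:,,1
A:11:,,8
A:12:,,1
A:13:,,1
A:14:,,40
A:15:,,1
A:16:,,1
A:17:,,1
A:18:,,1
A:19:,,1
A:20:,,6
A:21:,,1
A:22:,,19
A:23:,,1
A:24:,,1
A:25:,,1
A:26:,,1
A:27:,,1
A:28:,,1
A:29:,,6
A:30:,,17
A:31:,,0
A:32:,,2
A:33:,,3
A:34:,,1
A:35:,,1
A:36:,,1
A:37:,,1
A:38:,,15
A:39:,,2
A:40:,,1
A:41:,,1
A:42:,,1
A:43:,,1
A:44:,,1
A:45:,,1
A:46:,,12
A:47:,,3
A:48:,,1
A:49:,,3
A:50:,,2
A:51:,,3
A:52:,,1
A:53:,,11
A:54:,,7
A:55:,,1
A:56:,,1
A:57:,,1
A:58:,,1
A:59:,,2
A:60:,,1
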