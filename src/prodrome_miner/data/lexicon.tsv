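# surface	pos	category (optional)
呼吸困難	noun	respiratory
呼吸苦	noun	respiratory
息切れ	noun	respiratory
酸素	noun	respiratory
咳嗽	noun	respiratory
喀痰	noun	respiratory
疼痛	noun	pain_analgesic
痛み	noun	pain_analgesic
頭痛	noun	pain_analgesic
リリカ	noun	pain_analgesic
オキシコドン	noun	pain_analgesic
オキノーム	noun	pain_analgesic
オピオイド	noun	pain_analgesic
ロキソニン	noun	pain_analgesic
食欲不振	noun	appetite
食事摂取	noun	appetite
嘔気	noun	appetite
嘔吐	noun	appetite
ノバミン	noun	appetite
せん妄	noun	delirium
貧血	noun	anemia
出血	noun	bleeding
傾眠	noun	sleepiness
皮疹	noun	skin_eruption
発熱	noun
倦怠感	noun
不眠	noun
浮腫	noun
めまい	noun
口内炎	noun
便秘	noun
下痢	noun
不安	noun
睡眠	noun
疲労	noun
肺癌	noun
化学療法	noun
プレドニゾロン	noun
レスキュー	noun
体温	noun
体重	noun
血圧	noun
著変	noun
内服	noun
点滴	noun
診察	noun
検査	noun
家族	noun
経過	noun
病状	noun
緩和	noun
相談	noun
説明	noun
本日	noun
昨日	noun
明日	noun
今朝	noun
夜間	noun
mg	noun
mL	noun
37	noun
102	noun
あり	other
なし	other
です	other
ます	other
した	other
する	other
ため	other
にて	other
より	other
から	other
まで	other
こと	other
良好	other
が	other
は	other
を	other
の	other
と	other
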