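<?xml version='1.0' encoding='UTF-8'?>
<corpus>
  <post forum="bodyforum" thread="supplementen" id="p001" index="0" author="user042" timestamp="2016-03-01T10:15:00">
    <title>ervaring met Halodrol</title>
    <p n="0">Halodrol van Gaspari vandaag binnen gekregen.</p>
    <p n="1">Na een week merk ik vooral meer kracht tijdens de training.</p>
    <p n="2">Iemand anders ervaring hiermee?</p>
  </post>
  <post forum="bodyforum" thread="supplementen" id="p002" index="1" author="user007" timestamp="2016-03-02T21:40:00">
    <title>creatine vraagje</title>
    <p n="0">Ik gebruik creatine van Gaspari al een maand.</p>
    <p n="1">Verder geen last van mijn maag gelukkig.</p>
  </post>
</corpus>
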