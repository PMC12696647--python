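<fluxml name="mix">
  <metabolitepools>
    <pool id="A1" atoms="1"/>
    <pool id="A2" atoms="1"/>
    <pool id="B" atoms="1"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="A1" cfg="a"/><rproduct id="B" cfg="a"/></reaction>
    <reaction id="v2"><reduct id="A2" cfg="a"/><rproduct id="B" cfg="a"/></reaction>
    <reaction id="v3"><reduct id="B" cfg="a"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 &gt;= 0.1; v1 &lt;= 10; v2 &gt;= 0.1; v2 &lt;= 10</net>
  </constraints>
  <configuration id="exp1">
    <input pool="A1"><label cfg="1" purity="1.0"/></input>
    <input pool="A2"><label cfg="0" purity="1.0"/></input>
    <measurement>
      <group id="gB1" spec="B#M(1)" times="inf" sd="0.01"/>
    </measurement>
  </configuration>
  <configuration id="exp2">
    <input pool="A1"><label cfg="0" purity="1.0"/></input>
    <input pool="A2"><label cfg="1" purity="1.0"/></input>
    <measurement>
      <group id="gB2" spec="B#M(1)" times="inf" sd="0.01"/>
    </measurement>
  </configuration>
  <configuration id="kin">
    <input pool="A1"><label cfg="1" purity="1.0"/></input>
    <input pool="A2"><label cfg="0" purity="1.0"/></input>
    <measurement>
      <group id="gBk" spec="B#M(1)" times="0.5 1 2" sd="0.01"/>
    </measurement>
  </configuration>
</fluxml>
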